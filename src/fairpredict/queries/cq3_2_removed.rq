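PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX p-plan: <http://purl.org/net/p-plan#>
PREFIX prov: <http://www.w3.org/ns/prov#>
PREFIX dul: <http://www.ontologydesignpatterns.org/ont/dul/DUL.owl#>
PREFIX pwo: <http://purl.org/spar/pwo/>
PREFIX dcat: <http://www.w3.org/ns/dcat#>
PREFIX mls: <http://www.w3.org/ns/mls#>
PREFIX edam: <http://edamontology.org/>
PREFIX dc: <http://purl.org/dc/terms/>
PREFIX bpmn: <https://w3id.org/fair/plex/bpmn#>

# Instructions of the old version neither reused nor revised in the new one.
SELECT DISTINCT ?plan
WHERE {
  ?oldstep p-plan:isStepOfPlan ${old} ;
           dul:isDescribedBy ?plan .
  FILTER NOT EXISTS {
    ?newstep p-plan:isStepOfPlan ${new} ;
             dul:isDescribedBy ?plan .
  }
  FILTER NOT EXISTS {
    ?newplan prov:wasRevisionOf ?plan .
    ?newstep2 p-plan:isStepOfPlan ${new} ;
              dul:isDescribedBy ?newplan .
  }
}
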