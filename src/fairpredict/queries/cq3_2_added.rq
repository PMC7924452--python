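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

# Instructions of the new version neither reused from nor revising the old one.
SELECT DISTINCT ?plan
WHERE {
  ?newstep p-plan:isStepOfPlan ${new} ;
           dul:isDescribedBy ?plan .
  FILTER NOT EXISTS {
    ?oldstep p-plan:isStepOfPlan ${old} ;
             dul:isDescribedBy ?plan .
  }
  FILTER NOT EXISTS {
    ?plan prov:wasRevisionOf ?oldplan2 .
    ?oldstep2 p-plan:isStepOfPlan ${old} ;
              dul:isDescribedBy ?oldplan2 .
  }
}
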