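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

# Dataset distributions used by the new version but not by the old one.
SELECT DISTINCT ?dist
WHERE {
  ?newstep p-plan:isStepOfPlan ${new} ;
           dul:isDescribedBy ?newplan .
  ?newplan prov:qualifiedUsage ?u1 .
  ?u1 prov:entity ?dist .
  ?dist rdf:type dcat:Distribution .
  FILTER NOT EXISTS {
    ?oldstep p-plan:isStepOfPlan ${old} ;
             dul:isDescribedBy ?oldplan .
    ?oldplan prov:qualifiedUsage ?u2 .
    ?u2 prov:entity ?dist .
  }
  FILTER NOT EXISTS {
    ?dist prov:wasRevisionOf ?olddist2 .
    ?oldstep2 p-plan:isStepOfPlan ${old} ;
              dul:isDescribedBy ?oldplan2 .
    ?oldplan2 prov:qualifiedUsage ?u3 .
    ?u3 prov:entity ?olddist2 .
  }
}
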