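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

# Main steps of a workflow: the first step and everything it transitively precedes.
SELECT DISTINCT ?step
WHERE {
  ${workflow} pwo:hasFirstStep ?first .
  ?first dul:precedes* ?step .
}
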