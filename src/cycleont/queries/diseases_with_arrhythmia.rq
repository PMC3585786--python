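# Competency question 2c: diseases that co-occur with some arrhythmia.
# A disease instance inheres in a human whose heart participates in a
# beating process bearing an arrhythmic process attribute; the distinct
# disease classes are returned.
PREFIX rdf:  <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX cp:   <https://w3id.org/cycleont/pattern#>

SELECT DISTINCT ?disease WHERE {
    ?case    rdf:type            ?disease .
    ?disease rdfs:subClassOf     cp:Disease .
    ?case    cp:inheresIn        ?human .
    ?human   cp:hasPart          ?heart .
    ?heart   rdf:type            cp:Heart .
    ?heart   cp:participatesIn   ?beating .
    ?beating cp:hasProcessAttribute ?attr .
    ?attr    rdf:type            cp:ArrhythmicHeartRate .
}
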