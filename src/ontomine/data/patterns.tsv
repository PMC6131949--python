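template	observed_relation	predicate
[X] causes by [Y]	ns:medicine.disease.causes	http://schema.org/causeOf
[X] disability [Y]	ns:medicine.symptom.symptom_of	http://schema.org/signOrSymptom
[X] treatment of [Y]	treatrel.used_to_treat	http://schema.org/possibleTreatment
[X] drug treatment [Y]	treatrel.used_to_treat	http://schema.org/possibleTreatment
[X] cancer [Y]	ns:medicine.risk_factor.diseases	http://schema.org/diagnosis
example of [X] include [Y]	s:medicine.drug_class.drugs	http://schema.org/drug
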