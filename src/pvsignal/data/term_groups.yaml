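# Behavioral-addiction preferred-term groups used in the dopamine-agonist
# signal analysis.  Each group is a primary MedDRA-style preferred term plus
# clinically related preferred terms; compulsive shopping has no matching
# preferred term in the vocabulary and is therefore not evaluable.
binge_eating:
  primary_term: binge eating
  related_terms:
    - eating disorder
    - eating disorder symptom
    - bulimia
compulsive_shopping:
  primary_term: null
  related_terms: []
hypersexuality:
  primary_term: hypersexuality
  related_terms:
    - excessive masturbation
    - excessive sexual fantasies
    - exhibitionism
    - high-risk sexual behavior
    - libido increased
    - sexual abuse
    - sexual activity increased
    - sexual offense
pathological_gambling:
  primary_term: pathological gambling
  related_terms:
    - gambling
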