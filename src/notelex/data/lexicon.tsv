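term	stem	polarity_class	variants_note
adherent	adher	polarity_by_negation	adhere, adhered, adherence, adherent; non-/in- prefixed forms
aggressive	aggress	inherent_negative	aggressive, aggressively, aggression
agitated	agitat	inherent_negative	agitated, agitation, agitating, agitate
angry	angr	inherent_negative	angry, angrily
challenging	challeng	inherent_negative	challenging, challenged, challenge, challenges
combative	combative	inherent_negative	combative, combatively, combativeness
compliant	complian	polarity_by_negation	compliant, compliance; stem restricted to complian* so "complicated" never matches
confront	confront	inherent_negative	confront, confronts, confronted, confronting, confrontation, confrontational
cooperative	cooperat	polarity_by_negation	cooperative, cooperate, cooperated, cooperating, cooperation; non-/un- prefixed forms
defensive	defensiv	inherent_negative	defensive, defensively, defensiveness
exaggerate	exaggerat	inherent_negative	exaggerate, exaggerates, exaggerated, exaggerating, exaggeration
hysterical	hysteric	inherent_negative	hysterical, hysterically, hysterics
pleasant	pleasant	polarity_by_negation	pleasant, pleasantly; un- prefixed forms
refuse	refus	inherent_negative	refuse, refuses, refused, refusing, refusal, refusals
resist	resist	inherent_negative	resist, resists, resisted, resisting, resistant, resistance
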