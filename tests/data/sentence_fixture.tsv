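raw	expected
He is calm. She is angry.	He is calm.|She is angry.
Dr. Smith saw pt. Patient refused labs.	Dr. Smith saw pt.|Patient refused labs.
The pt. reports nausea this morning.	The pt. reports nausea this morning.
Mrs. Jones denies chest pain. Will follow up.	Mrs. Jones denies chest pain.|Will follow up.
Mr. Lee was seen by Dr. Patel today.	Mr. Lee was seen by Dr. Patel today.
Temp 98.6 F. Pulse 72 regular.	Temp 98.6 F. Pulse 72 regular.
Na 140 and K 4.0 on repeat labs.	Na 140 and K 4.0 on repeat labs.
ASSESSMENT: Stable overnight. Continue current plan.	ASSESSMENT:|Stable overnight.|Continue current plan.
PLAN: Discharge home tomorrow.	PLAN:|Discharge home tomorrow.
HPI: Admitted with shortness of breath.	HPI:|Admitted with shortness of breath.
Is he improving? Yes, slowly.	Is he improving?|Yes, slowly.
Call if symptoms worsen!	Call if symptoms worsen!
Patient seen at 10 a.m. and again at 2 p.m. today.	Patient seen at 10 a.m. and again at 2 p.m. today.
Compared vs. prior imaging, no change.	Compared vs. prior imaging, no change.
J. Smith is the attending physician.	J. Smith is the attending physician.
Meds reviewed, e.g. aspirin and statin.	Meds reviewed, e.g. aspirin and statin.
Continue home meds, i.e. metformin.	Continue home meds, i.e. metformin.
Wound care daily. - elevate leg - keep dressing dry	Wound care daily.|- elevate leg|- keep dressing dry
Plan: rest. Follow up in clinic.	Plan: rest.|Follow up in clinic.
She denies fever. She denies chills. She denies cough.	She denies fever.|She denies chills.|She denies cough.
No acute events overnight.	No acute events overnight.
Discharged in stable condition...	Discharged in stable condition...
Labs pending. Imaging pending. Will reassess.	Labs pending.|Imaging pending.|Will reassess.
MEDS: lisinopril 10 mg daily. Tolerating well.	MEDS:|lisinopril 10 mg daily.|Tolerating well.
Pt. Family at bedside.	Pt.|Family at bedside.
He eats well. Sleeps poorly.	He eats well.|Sleeps poorly.
Was the test positive? It was not.	Was the test positive?|It was not.
CT head negative. MRI deferred.	CT head negative.|MRI deferred.
Follow up with Dr. Wu in 2 weeks.	Follow up with Dr. Wu in 2 weeks.
Ms. Li ambulating independently.	Ms. Li ambulating independently.
Creatinine 1.2 from 1.5 yesterday.	Creatinine 1.2 from 1.5 yesterday.
Weight 80.5 kg today. Up 1.5 kg.	Weight 80.5 kg today.|Up 1.5 kg.
ROS: otherwise negative.	ROS:|otherwise negative.
Stable on room air. No distress noted.	Stable on room air.|No distress noted.
Rechecked at 3 p.m. without change.	Rechecked at 3 p.m. without change.
Awaiting placement. Social work following.	Awaiting placement.|Social work following.
Diet advanced. Tolerated well!	Diet advanced.|Tolerated well!
Home O2 arranged. Teaching completed.	Home O2 arranged.|Teaching completed.
Daughter updated by phone. Agreeable to plan.	Daughter updated by phone.|Agreeable to plan.
Blood cultures drawn. Results pending.	Blood cultures drawn.|Results pending.
What brought him in? Worsening edema.	What brought him in?|Worsening edema.
Seen with interpreter. Questions answered.	Seen with interpreter.|Questions answered.
Incision clean. Dry. Intact.	Incision clean.|Dry.|Intact.
Prognosis discussed at length.	Prognosis discussed at length.
Transfer orders written. Bed requested.	Transfer orders written.|Bed requested.
INR 2.3 today. Continue warfarin.	INR 2.3 today.|Continue warfarin.
Fall precautions in place. PT consulted.	Fall precautions in place.|PT consulted.
Echo shows EF 55 percent. No effusion.	Echo shows EF 55 percent.|No effusion.
Goals of care discussed. Full code confirmed.	Goals of care discussed.|Full code confirmed.
Rash improving. Steroid taper continues.	Rash improving.|Steroid taper continues.
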