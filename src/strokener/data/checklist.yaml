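# Thrombolysis eligibility checklist used for report grouping.  Items carry
# display text, the required answer (polarity), and the ontology entities whose
# detection is relevant to the item.  Numeric thresholds (BP, PT, platelets,
# glucose, INR) are display text only; the toolkit performs no numeric
# extraction or question answering.
version: 1
items:
  - text: "Does the patient have symptoms of acute stroke?"
    polarity: must-be-yes
    entities: [stroke, ischaemic-stroke, weakness, speech-disturbance, visual-loss, sensation-loss]
  - text: "Is there a measurable deficit on the NIH scale?"
    polarity: must-be-yes
    entities: [weakness, speech-disturbance, visual-loss, ataxia]
  - text: "Was the patient previously independent?"
    polarity: must-be-yes
    entities: [requires-help, impaired-mobility, long-term-placement]
  - text: "Is there a clear time of onset within the last 4 ½ hours?"
    polarity: must-be-yes
    entities: []
  - text: "Has a CT scan since stroke onset excluded haemorrhage?"
    polarity: must-be-yes
    entities: []
  - text: "Has a senior member of the stroke team reviewed the CT scan?"
    polarity: must-be-yes
    entities: []
  - text: "Has the patient suffered head trauma or stroke within the last 3 months?"
    polarity: must-be-no
    entities: [head-trauma, trauma-unspecified, stroke, ischaemic-stroke, transient-ischaemic-attack]
  - text: "Has the patient undergone major surgery within the past 2 weeks?"
    polarity: must-be-no
    entities: [surgical-procedure]
  - text: "Is there a past history of intracranial haemorrhage?"
    polarity: must-be-no
    entities: [intracranial-haemorrhage, subarachnoid-haemorrhage, subdural-haemorrhage,
               extradural-haemorrhage, brain-haemorrhage-unspecified]
  - text: "Is the history suggestive of SAH?"
    polarity: must-be-no
    entities: [subarachnoid-haemorrhage, headache, neck-stiffness]
  - text: "Is the systolic BP >185 mmHg (after treatment if necessary)?"
    polarity: must-be-no
    entities: [hypertension]
  - text: "Is the diastolic BP >110 mmHg (after treatment if necessary)?"
    polarity: must-be-no
    entities: [hypertension]
  - text: "Has there been any GI or urinary tract haemorrhage within the last 21 days?"
    polarity: must-be-no
    entities: [non-brain-haemorrhage, gastrointestinal-ulceration]
  - text: "Has there been an arterial puncture at a non compressible site within the last 7 days?"
    polarity: must-be-no
    entities: [other-invasive-procedure]
  - text: "Was there a seizure at the time of symptom onset?"
    polarity: must-be-no
    entities: [seizure, epilepsy, todds-paresis]
  - text: "Is the patient on full dose anticoagulant treatment (e.g. warfarin with INR >1.5, therapeutic dose heparin/LMWH or oral thrombin inhibitor such as dabigatran, rivoroxaban)?"
    polarity: must-be-no
    entities: [warfarin, heparin, dabigatran, rivaroxaban, apixaban, edoxaban, other-anticoagulant]
  - text: "Is the PT >15 sec (for those not on anticoagulants)?"
    polarity: should-be-no
    entities: [clotting-condition, bleeding-condition]
  - text: "Is the platelet count <100,000?"
    polarity: should-be-no
    entities: [bleeding-condition]
  - text: "Is the plasma glucose <2.7 or >22.2 mmol/l?"
    polarity: should-be-no
    entities: [hypoglycaemia, diabetes-mellitus]
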