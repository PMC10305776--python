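# Entity-free filler sentences for the synthetic letter generator, one per line.
# These provide O-tagged context between entity-bearing sentences and must not
# contain any ontology surface form.
Routine observations were stable throughout the admission.
Bloods on admission were unremarkable.
A follow up appointment has been arranged in six weeks.
Thank you for seeing this patient at your earliest convenience.
The family were updated by the ward team.
Imaging was reviewed at the weekly meeting.
He was seen by the physiotherapy team prior to discharge.
The GP will continue routine monitoring.
She remained well during the period of observation.
Outpatient review is planned for next month.
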