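# Sentence templates for the synthetic letter generator, one per line.
# The token {E} marks the entity slot.  Every template keeps at least five
# tokens (words or punctuation) on each side of the slot so that the
# +/-5-token context window of a generated mention stays inside its own
# sentence, and the slot is always bounded by whitespace or punctuation so
# generated spans fall on token boundaries.
The past medical history includes {E} according to the referral letter.
There is a documented history of {E} noted in the primary care record.
The patient was commenced on {E} by the community team last year.
He was admitted in 2016 with {E} and made a good recovery.
On examination there was evidence of {E} which has since fully resolved.
She reports several episodes of {E} over the last six months.
The general practitioner is concerned about {E} as documented in the referral.
There have been no further episodes of {E} since the most recent discharge.
The current medication list includes {E} at the usual maintenance dose.
A long standing background of {E} is managed in primary care.
The family are increasingly concerned about {E} over the past few weeks.
He was discharged home following treatment for {E} under the medical team.
The referral letter also mentions previous {E} from several years ago.
The ward round note documents {E} on the active problem list.
Assessment in the clinic today revealed {E} of relatively recent onset.
The nursing staff observed intermittent {E} during the period of admission.
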