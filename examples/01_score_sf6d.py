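"""Score SF-36 questionnaire answers with the SF-6D utility model.

Recodes one respondent's SF-36 items to the six SF-6D dimensions, applies
the additive UK valuation (constant 1, level decrements, MOST penalty), and
converts the utility to QALYs over half a year.
"""

from copdcua import SF36Response, recode_sf36_to_sf6d, score_sf6d, utility_to_qaly

# a moderately limited respondent: slight vigorous-activity limitation,
# work limited by physical health, some pain, occasional low mood
answers = dict(q3a=2, q3b=3, q3j=3, q4c=1, q5b=2, q7=3, q8=2,
               q9b=5, q9e=4, q9f=6, q10=4)

classification = recode_sf36_to_sf6d(SF36Response(answers, visit="month6"))
utility = score_sf6d(classification)
qaly_half_year = utility_to_qaly(utility, 0.5)

print(f"SF-6D levels (PF,RL,SF,PAIN,MH,VIT): {classification.levels()}")
print(f"utility:            {utility:.3f}")
print(f"QALYs over 26 weeks: {qaly_half_year:.4f}")
print()
print("A utility of 1 is full health; each dimension level above 1 subtracts")
print("its valuation decrement, so this respondent loses about 0.3 QALY-weight")
print("relative to full health.")
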