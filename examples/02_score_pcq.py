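"""Score raw PCQ item answers into subscale and total scores.

The negative-consequence PCQ sums 0-3 item answers: 5 emotional items
(0-15), 4 physical items (0-12), 3 social items (0-9); the total (0-36)
is the sum of the subscales.
"""

from screenlasso import PcqItemResponse, score_pcq

resp = PcqItemResponse(
    emotional_items=[1, 0, 2, 0, 1],
    physical_items=[0, 0, 0, 1],
    social_items=[3, 0, 0],
    respondent="R001",
)
scores = score_pcq(resp)
print(f"emotional={scores.emotional} physical={scores.physical} "
      f"social={scores.social} total={scores.total}")

partial = PcqItemResponse(
    emotional_items=[2, 2, 2, 2, None],  # one item skipped
    physical_items=[0, 0, 0, 0],
    social_items=[0, 0, 0],
)
print("default rule (complete cases):", score_pcq(partial))
print("prorated:", score_pcq(partial, missing_rule="prorate"))
print()
print("By default a skipped item makes the whole case missing; prorating")
print("substitutes the subscale mean when at least half the items are answered.")
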