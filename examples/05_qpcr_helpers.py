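"""Delta-delta-Cq fold changes and percent-of-input arithmetic.

The small helpers behind the qPCR figures: relative expression with
multi-reference normalization, and IP recovery expressed as a percentage of
the pre-IP input aliquot.
"""

from pausewave import ddcq_fold_change, percent_of_input

# target comes up 1.2 cycles earlier in the test sample, references stable
fold = ddcq_fold_change(
    cq_target_test=18.8,
    cq_target_control=20.0,
    cq_ref_test=[17.1, 19.3, 16.8],
    cq_ref_control=[17.0, 19.4, 16.8],
    efficiency=2.0,
)
print(f"ddCq fold change (3 references): {fold:.2f}")
print("(> 1: the target is up in the test condition after reference "
      "normalization)")

# RNA-IP: 1% of lysate kept as input; IP comes up 5.6 cycles after input
pct = percent_of_input(cq_ip=25.6, cq_input=20.0, input_fraction=0.01,
                       efficiency=2.0)
print(f"percent of input recovered by the IP: {pct:.3f}%")

# with a no-antibody background
pct_bg = percent_of_input(cq_ip=25.6, cq_input=20.0, input_fraction=0.01,
                          efficiency=2.0, cq_background=29.0)
print(f"background-subtracted:                {pct_bg:.3f}%")
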