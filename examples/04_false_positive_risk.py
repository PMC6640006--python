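"""Monte-Carlo false positive risk for the amblyopia-vs-control comparison.

An observed p-value alone does not say how likely the finding is to be a
false positive.  This simulation assumes the control (null) AULCSF
population N(1.65, 0.147) and the amblyopic alternative N(0.99, 0.467),
replays the experiment 100,000 times under each hypothesis (n = 11 test
sample vs n = 24 reference, Welch t-test), and counts in each arm how
often a p-value within a factor 2 of the observed 0.0009 occurs.
"""

from qcsf import FPRConfig, fpr_simulation

config = FPRConfig(
    null_mean=1.65, null_sd=0.147,
    alt_mean=0.99, alt_sd=0.467,
    n_test=11, n_ref=24,
    n_sim=100_000, observed_p=0.0009, band_factor=2.0,
    seed=1,
)
result = fpr_simulation(config)

print(f"replicates per arm          : {config.n_sim:,}")
print(f"null arm, p in band         : {result.m_null}")
print(f"alternative arm, p in band  : {result.m_alt}")
print(f"null arm, p <= {config.observed_p}      : {result.null_tail_count}")
print(f"false positive risk         : {result.fpr:.4f}")
print(
    "\nAbout 90 of 100,000 null replicates reach p <= 0.0009 (the p-value\n"
    "is calibrated), but the alternative hypothesis produces p-values in\n"
    "the band hundreds of times more often, so the chance the observed\n"
    "comparison was a null fluke is only a few parts in a thousand."
)
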