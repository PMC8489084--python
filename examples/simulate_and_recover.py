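"""Simulate two-sample summary statistics and recover the planted truth.

Generates an instrument panel at the precision scale of the bundled
25-hydroxyvitamin D study with a known causal effect and one gross
pleiotropic outlier, then shows MR-PRESSO flagging the planted variant and
the outlier-corrected IVW estimate moving toward the truth.
"""

from tsmr import harmonize, ivw, mr_presso, simulate_pair, table1_like_config

TRUE_BETA = 0.25

cfg = table1_like_config(
    "25OHD", true_beta=TRUE_BETA, seed=11, n_outliers=1, outlier_shift=0.30
)
pair = simulate_pair(cfg, seed=5)
data = harmonize(pair.exposure, pair.outcome)

planted = pair.exposure[pair.truth.outlier_indices[0]].rsid
print(f"true causal effect (log-odds per SD): {TRUE_BETA}")
print(f"planted outlier: {planted} (+0.30 direct effect, ~10 outcome SEs)\n")

raw = ivw(data)
print(f"raw IVW estimate:       {raw.beta:+.3f} (se {raw.se:.3f})")

res = mr_presso(data, n_sim=1000, seed=5)
print(f"MR-PRESSO global p:     {res.global_pvalue:.4f}")
print(f"flagged outliers:       {res.outlier_rsids}")
if res.corrected_estimate is not None:
    c = res.corrected_estimate
    print(f"outlier-corrected IVW:  {c.beta:+.3f} (se {c.se:.3f})")
    print("\nThe corrected estimate discards the planted variant and sits "
          "closer to the true effect than the contaminated raw estimate.")
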