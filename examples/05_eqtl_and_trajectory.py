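"""Clade dosage as a cis-eQTL, and the ancient-sample frequency trajectory.

Simulates expression with variance explained 0.235 per clade-2 dosage,
fits the additive regression, then bins dated ancient samples and checks
that the clade-2 frequency has been flat through time.
"""

from haplodistill import (
    CladeAssignment,
    SimParams,
    beta_for_r2,
    core_haplotypes,
    dosage_code,
    fit_additive,
    simulate_ancient_samples,
    simulate_expression,
    simulate_two_clade,
    temporal_trajectory,
)

r = simulate_two_clade(SimParams(seed=1, L=70_000))
m = r.matrix
asn = CladeAssignment(dict(r.truth.clade_labels), "truth")

dosages, dropped = dosage_code(m, asn)
beta = beta_for_r2(0.235, sigma=1.0, clade2_freq=0.325)
expr = simulate_expression(dosages, beta=beta, sigma=1.0, seed=3)
fit = fit_additive(dosages, expr)
print(f"eQTL: beta={fit.beta:.3f} (true {beta:.3f}), r2={fit.r_squared:.3f}, "
      f"p={fit.p:.2e}, n={fit.n}")

stem_idx = [i for i, v in enumerate(m.variants)
            if v.pos in set(r.truth.stem_positions)]
core = core_haplotypes(m.subset_rows(stem_idx), asn)
tags = list(core["vid"].iloc[:15])
orient = {row.vid: int(row.clade2_allele) for row in core.itertuples()
          if row.vid in set(tags)}
ancient = simulate_ancient_samples(lambda age: 0.30, orient,
                                   n_per_bin=10, missing_rate=0.2, seed=4)
traj = temporal_trajectory(ancient, core, tags)
occ = traj.dropna(subset=["clade2_freq_pct"])
print(f"ancient samples: {len(ancient)}; occupied bins: {len(occ)}")
print(f"mean clade-2 frequency through time: {occ['clade2_freq_pct'].mean():.1f}% "
      f"(simulated at 30%)")
# A positive beta with r2 near 0.235 mirrors a moderate-effect cis-eQTL;
# a flat ~30% trajectory over 45,000 years is the signature of long-term
# balancing selection rather than a recent sweep.
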