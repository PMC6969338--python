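"""Within-twin correlations and the MZ-vs-DZ Fisher r-to-z comparison.

A phenotype more alike in monozygotic (MZ) than dizygotic (DZ) pairs
points to genetic influence.  The Fisher transform z = atanh(r) makes
the two independent correlations comparable by a normal-theory test.
"""

from twinscan import (
    fisher_z_compare,
    generate_twin_phenotypes,
    within_twin_correlation,
)

# heritable phenotype: A = 0.65, C = 0, E = 0.35
tab = generate_twin_phenotypes(129, 108, 0.65, 0.0, 0.35, seed=42)
rmz = within_twin_correlation(tab, "MZ")
rdz = within_twin_correlation(tab, "DZ")
res = fisher_z_compare(rmz.r, rmz.n, rdz.r, rdz.n)
print(f"simulated cohort:  rMZ = {rmz.r:.2f} (n={rmz.n}), "
      f"rDZ = {rdz.r:.2f} (n={rdz.n})")
print(f"                   Z = {res.z:.2f}, p = {res.p:.2g}")

# The same computation on published correlations reproduces published
# statistics: rMZ = .70 vs rDZ = .17 at 129/108 complete pairs.
res = fisher_z_compare(0.70, 129, 0.17, 108)
print(f"published inputs:  Z = {res.z:.2f}, p = {res.p:.2g}  (printed: 5.27)")
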