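"""Neighbouring-gene pairs: independent versus coordinated silencing.

Two-color experiments on closely linked loci ask whether silencing on the
inactivatable chromosome is coordinated.  Under independence the fraction of
nuclei biallelic at both loci is the product of the marginal biallelic
fractions; a significant excess means regional coordination.  The simulator
couples silencing states with ρ (0 = independent, 1 = identical), so both
regimes can be generated and recovered.
"""
import allelefish as af
from allelefish.data import LocusClass

for rho, label in ((0.0, "independent (rho = 0)"), (1.0, "coordinated (rho = 1)")):
    config = af.SimConfig(
        loci=(
            af.SimLocus("gA", LocusClass.SEX_SPECIFIC, 0.40, 0.98),
            af.SimLocus("gB", LocusClass.SEX_SPECIFIC, 0.45, 0.97),
        ),
        pairs=(af.SimPair("gA", "gB", rho),),
        n_homogametic=250,
        tetraploid_fraction=0.0,
        colocation_fidelity=0.96,
        seed=11,
    )
    records = af.simulate_pair_population(config, ("gA", "gB"))
    # marginal biallelic fractions as measured in single-probe experiments
    f2_a = 0.98**2 * (1 - 0.40)
    f2_b = 0.97**2 * (1 - 0.45)
    result = af.score_pair(records, "gA/gB", f2_a, f2_b, family_size=2)
    print(f"--- {label} ---")
    print(f"co-location among both-monoallelic nuclei: "
          f"{result.colocation_fraction:.2f} (n = {result.n_both_monoallelic})")
    print(f"joint biallelic: observed {result.observed_joint_pct:.1f}% "
          f"vs expected {result.expected_joint_pct:.1f}%")
    print(f"chi2 = {result.chi2:.2f}, corrected p = {result.p_adj:.3g}")
    print(f"regime: {result.regime.value}")
    print()

print("High co-location in both regimes reflects a single active chromosome;")
print("only the joint-biallelic excess distinguishes coordinated escape.")
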