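"""Monte-Carlo power of the two LD tests under multinomial sampling.

At fixed true haplotype frequencies corresponding to D' = 1 with both major
alleles at 0.9, haplotypes are resampled and the fraction of replicates in
which each test rejects equilibrium is reported per sample size.  Small
samples cannot detect even perfect LD; the null case shows both tests hold
their level.
"""

import lrldscan as L

FULL_LD = (0.9, 0.0, 0.0, 0.1)          # D' = 1
EQUILIBRIUM = (0.81, 0.09, 0.09, 0.01)  # same margins, no LD

print("detection rate at D' = 1 (10,000 replicates, alpha = 0.05)")
print(f"{'n':>6} {'chi2':>8} {'fisher':>8}")
for n in (25, 50, 100, 500):
    res = L.simulate_detection_rate(FULL_LD, n=n, n_reps=10_000, seed=0)
    print(f"{n:>6} {res.rate_chi2:>8.3f} {res.rate_fisher:>8.3f}")

print("\ndetection rate across the haplotype-frequency range (partial D'):")
print(f"{'p_AB':>6} {'D-prime':>8} {'n=25':>8} {'n=500':>8}")
for p_ab in (0.82, 0.84, 0.86, 0.88, 0.90):
    freqs = (p_ab, 0.9 - p_ab, 0.9 - p_ab, p_ab - 0.8)
    dprime = (p_ab - 0.81) / 0.09
    small = L.simulate_detection_rate(freqs, n=25, n_reps=10_000, seed=1)
    large = L.simulate_detection_rate(freqs, n=500, n_reps=10_000, seed=1)
    print(f"{p_ab:>6.2f} {dprime:>8.2f} {small.rate_chi2:>8.3f} {large.rate_chi2:>8.3f}")
print("-> with 25 individuals, weak-to-moderate LD goes largely undetected.")

null = L.simulate_detection_rate(EQUILIBRIUM, n=500, n_reps=10_000, seed=0)
print(
    f"\nnull rejection rate at n=500: chi2 {null.rate_chi2:.4f}, "
    f"fisher {null.rate_fisher:.4f} (nominal 0.05; MC SE ~ {null.mc_se_chi2:.4f})"
)
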