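"""Two-stage GWAS by backsolving marker effects from genomic predictions.

A single large-effect QTL is planted on a polygenic background; the
backsolved additive effects and their standard errors produce -log10(p)
scores, and the discovery threshold divides the 0.05 level by the
effective number of markers.
"""

import numpy as np

import polyblup as pb

ms = pb.sim_population(n=250, m=600, ploidy=4, seed=41)
truth = pb.sim_genetic_values(ms, sigma2_A=0.3, sigma2_D=0.0, mu_beta=0.0,
                              sigma2_gE=0.3, seed=42)
k_qtl = 250
truth.additive = truth.additive + 1.2 * ms.W[:, k_qtl]
_, s1 = pb.sim_phenotypes(ms, truth, n_envs=3, seed=43)

fit = pb.fit_stage2(s1, pb.Stage2Spec(model="additive-residual"), geno=ms)
state = pb.blup_prep(fit)
eff = pb.marker_effects(state, what="AV")
tab, thr = pb.gwas_scores(eff, state, what="AV", level=0.05)

top = tab.loc[tab["score"].idxmax()]
print(f"markers tested: {len(tab)}")
print(f"threshold: -log10(0.05 / m_eff) = {thr:.2f}")
print(f"planted QTL: {ms.marker_ids[k_qtl]} on {ms.chrom[k_qtl]}")
print(f"top score:   {top['marker']} on {top['chrom']} "
      f"(score {top['score']:.2f}, effect {top['additive']:+.3f})")
print(f"significant markers: {int(tab['significant'].sum())}")
print("a hit at or near the planted marker (its chromosome) indicates the "
      "backsolve localizes the QTL; LD with neighbors can share the signal")
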