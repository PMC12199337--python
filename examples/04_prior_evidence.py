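"""Weight heterogeneous prior evidence for TF-target edges.

Shows the four evidence channels: curated literature (publication count,
assay class, interaction type), ChIP-seq binding (distance decay around
the TSS), motif scans (conservation-weighted significance) and knockout
differential expression.
"""

from tfactnet.prior import (
    ChipEvidence,
    CuratedEvidence,
    KnockoutEvidence,
    MotifEvidence,
    chip_weight,
    curated_weight,
    knockout_edges,
    median_distance,
    motif_weight,
)

print("curated: 5 publications, targeted assay, direct interaction")
ev = CuratedEvidence("GATA1", "KLF1", n_publications=5,
                     method_class="small_mid", interaction_type="direct")
print(f"  weight = {curated_weight(ev):.3f}   (1.0 = maximal credit)")

ev = CuratedEvidence("GATA1", "EPOR", n_publications=1,
                     method_class="high_throughput", interaction_type="unknown")
print("curated: single high-throughput observation, type unknown")
print(f"  weight = {curated_weight(ev):.3f}")

print("\nChIP-seq: three binding sites at 0 / 500 / 2000 bp from the TSS,")
d_tf = median_distance([100, 500, 800, 2000, 5000])
w = chip_weight(ChipEvidence("GATA1", "KLF1", [0, 500, 2000]), d_tf=d_tf)
print(f"TF median site distance {d_tf:.0f} bp -> weight = {w:.3f} "
      "(each site adds exp(-d/D))")

print("\nmotif: FIMO p = 1e-5, phastCons 0.9, phyloP 2.0")
w = motif_weight(MotifEvidence("GATA1", "KLF1", fimo_p=1e-5,
                               phastcons=0.9, phylop=2.0))
print(f"  weight = {w:.3f} = sqrt(0.9 * 2.0 * 5)")

print("\nknockout: TF down (p=1e-4, logFC=-2.3); two candidate targets")
edges = knockout_edges([
    KnockoutEvidence("ds1", "GATA1", 1e-4, -2.3, "KLF1", 0.001, -1.8),
    KnockoutEvidence("ds1", "GATA1", 1e-4, -2.3, "ACTB", 0.4, -0.1),
])
for r, t, w in edges:
    print(f"  {r} -> {t}: weight {w:.2f} (= -log10 of the target's DE p)")
print("  ACTB excluded: not differentially expressed.")
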