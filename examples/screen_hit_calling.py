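"""Primary RNAi screen analysis: NPI, plate QC and hit calling.

Simulates triplicate viability plates for 40 genes across HMEC and four
malignant lines with ten planted malignant-selective dependencies (NPI 40)
and five pan-lethal genes (NPI 60 everywhere), then derives the effect
threshold from negative controls and calls hits with the primary rule.
"""

from genedep import screen
from genedep.simulate import ScreenSimConfig, simulate_screen

malignant = ["BCCL01", "BCCL02", "BCCL03", "BCCL04"]
selective = [f"G{i:04d}" for i in range(10)]
lethal = [f"G{i:04d}" for i in range(35, 40)]
hits = [(g, l, 40.0, 5.0) for g in selective for l in malignant]
hits += [(g, l, 60.0, 5.0) for g in lethal for l in malignant + ["HMEC"]]

data = simulate_screen(ScreenSimConfig(seed=7, planted_hits=hits))
wells, plate_qc = screen.annotate_npi(data.plates)
print(f"plates: {len(plate_qc)}, all Z' valid (>= 0.3): {plate_qc['valid'].all()}")
print(f"mean plate Z': {plate_qc['zprime'].mean():.3f}")

gene_line, qc = screen.summarize_gene_line(wells)
neg_npi = wells.loc[wells["reagent_type"] == "neg_ctrl", "npi"]
thr = screen.hit_threshold(neg_npi.to_numpy())
print(f"negative-control NPI: {neg_npi.mean():.2f}% +/- {neg_npi.std(ddof=1):.2f}")
print(f"effect threshold (mean + 3 SD): {thr:.2f}% NPI")

calls = screen.call_primary_hits(gene_line, thr)
called = set(calls.index[calls["verdict"] == "hit"])
print(f"hits called: {len(called)}")
print(f"  planted selective recovered: {len(called & set(selective))}/10")
print(f"  pan-lethal correctly rejected: {5 - len(called & set(lethal))}/5")
print(f"  false positives among nulls: {len(called - set(selective) - set(lethal))}")
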