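"""Find pedigree fingerprint sites in a synthetic cohort, end to end.

Simulates a 20-member pedigree beside a 410-accession background with 20
planted pedigree-specific sites, writes the cohort as VCF + manifest, then
runs the two-part workflow: VCF -> presence/absence matrix -> TF-IDF scores,
with a permutation-derived selection threshold.
"""

import tempfile
from pathlib import Path

from fpfinder import (CohortSpec, NullSimulationSpec, SampleManifest,
                      build_matrix, pedigree_threshold, read_vcf,
                      recovery_report, score_sites, simulate_cohort)

workdir = Path(tempfile.mkdtemp(prefix="fpfinder_"))
spec = CohortSpec(n_target=20, n_sites=5000, n_planted_pedigree=20, seed=42)
paths = simulate_cohort(spec).write(workdir)
print(f"cohort: {spec.n_sites} sites, 20 pedigree + {spec.n_background} background samples")

# part 1: VCF -> presence/absence matrix (QUAL < 30 trimmed)
records = read_vcf(paths["vcf"], min_qual=30)
print(f"retained {records.n_sites} sites after the quality filter "
      f"(dropped: {records.dropped})")
matrix = build_matrix(records, SampleManifest.read(paths["manifest"]))

# part 2: TF-IDF score of every site for the pedigree vs the background
manifest = SampleManifest.read(paths["manifest"])
results = score_sites(matrix, manifest)
thr = pedigree_threshold(NullSimulationSpec(n_target=20, n_background=410,
                                            n_sims=1000, top_fraction=0.05, seed=42))
selected = results[results["score"] >= thr]
print(f"permutation threshold (top 5% of 1000 null scores): {thr:.3f}")
print(f"fingerprint sites at that threshold: {len(selected)}")

truth = Path(paths["truth"])
import pandas as pd
rep = recovery_report(pd.read_csv(truth, sep="\t"), results, thr)
print(f"planted-site recovery: recall {rep.recall:.2f}, precision {rep.precision:.2f}")
print("a recall/precision of 1.00 means the selected set is exactly the 20 planted"
      " pedigree-specific sites")
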