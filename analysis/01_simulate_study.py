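#!/usr/bin/env python
"""Generate the synthetic pooled-cartilage study used by the downstream steps.

Emulates the deposited design: 8 pooled samples (WT/KO x sham/DMM x weeks
2/4, one pool per cell), 2000 genes of which 5% are planted "attenuated"
(positive DMM response in WT, suppressed in KO), 10% respond equally in
both genotypes, and 10% sit below the TPM filter.  Writes the matrix,
sample sheet, planted truth, a fixture hallmark-style GMT and an
identity-like ortholog map under results/synthetic_study/.
"""

from pathlib import Path

from difsel import SimulationConfig, make_fixture_collections, simulate_study
from difsel.io import write_expression_matrix, write_gmt, write_ortholog_map
from difsel.simulate import write_truth

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic_study"


def main() -> None:
    cfg = SimulationConfig()  # the study conditions; seed fixed at 7
    matrix, truth = simulate_study(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(matrix, OUT / "matrix.tsv", OUT / "samples.tsv")
    write_truth(truth, OUT / "truth.tsv")
    collection, omap = make_fixture_collections(truth, n_sets=10, set_size=50,
                                                seed=cfg.seed)
    write_gmt(collection, OUT / "sets.gmt")
    write_ortholog_map(omap, OUT / "orthologs.tsv")
    classes = truth.table["class"].value_counts().to_dict()
    print(f"simulated {cfg.n_genes} genes x 8 samples -> {OUT}")
    print(f"planted classes: {classes}")


if __name__ == "__main__":
    main()
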