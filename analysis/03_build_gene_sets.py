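#!/usr/bin/env python
"""Functional and altered gene sets from CNAs + expression.

Annotates genes on the recurrent regions, keeps those whose expression
moves with the alteration (one-sided Welch, P < 0.05) as the FGS, reduces
to the direction-pure common FGS, and builds the per-patient (top/bottom
100 cross-sample ranks) and common (recurrent in >= 5 patients) AGS.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dgscore import io as dio
from dgscore.config import PipelineConfig
from dgscore.pipeline import load_cohort, run_on_cohort


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--literature-genes", type=Path, default=None)
    args = ap.parse_args()

    cfg = PipelineConfig(
        probe_map=str(args.indir / "probe_map.tsv"),
        log_ratios=str(args.indir / "log_ratios.tsv"),
        expression=str(args.indir / "expression.tsv"),
        gene_annotation=str(args.indir / "gene_annotation.tsv"),
        network=str(args.indir / "network.tsv"),
        clinical=str(args.indir / "clinical.tsv"))
    lit = (dio.read_literature_genes(args.literature_genes)
           if args.literature_genes else None)
    res = run_on_cohort(load_cohort(cfg), cfg, literature_genes=lit,
                        run_survival=False)

    h = cfg.hash()
    dio.write_gene_set(res.fgs.gene_set, args.outdir / "fgs_full.tsv", h)
    dio.write_gene_set(res.fgs_common, args.outdir / "fgs_common.tsv", h)
    dio.write_gene_set(res.ags_common, args.outdir / "ags_common.tsv", h)

    n_ann = len(res.fgs.annotated_genes)
    print(f"{n_ann} genes annotated on {len(res.regions)} recurrent regions")
    print(f"FGS: {len(res.fgs.gene_set)} concordant genes "
          f"({len(res.fgs.gene_set) / max(1, n_ann):.1%} of annotated)")
    print(f"common FGS (direction-pure regions only): {len(res.fgs_common)}")
    print(f"common AGS: {len(res.ags_common)} genes "
          f"(recurrent in >= {cfg.common_ags_min_recurrence} patient AGS"
          + (f", + literature list" if lit else "") + ")")


if __name__ == "__main__":
    main()
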