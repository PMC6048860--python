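#!/usr/bin/env python
"""Per-patient CNA calling and recurrent-region detection.

Segments every patient's probe log2-ratios (penalized least-squares
changepoints), applies the published CNA filters (gain/loss at +-0.15,
FDR <= 1e-05, >= 1 kb, >= 10 probes), and reports regions altered in at
least 10% of patients.  Writes segments.tsv, cnas.tsv and regions.bed.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dgscore import io as dio
from dgscore.config import PipelineConfig
from dgscore.pipeline import _segmentation_params, load_cohort, segment_cohort
from dgscore.segmentation import detect_recurrent_regions, filter_segments


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cfg = PipelineConfig(
        probe_map=str(args.indir / "probe_map.tsv"),
        log_ratios=str(args.indir / "log_ratios.tsv"),
        expression=str(args.indir / "expression.tsv"),
        gene_annotation=str(args.indir / "gene_annotation.tsv"),
        network=str(args.indir / "network.tsv"),
        clinical=str(args.indir / "clinical.tsv"))
    cohort = load_cohort(cfg)
    params = _segmentation_params(cfg)

    segs = segment_cohort(cohort.probe_map, cohort.log_ratios, params)
    cnas = {p: filter_segments(s, params) for p, s in segs.items()}
    n_cnas = [len(v) for v in cnas.values()]
    regions = detect_recurrent_regions(cnas, len(cnas), cohort.probe_map,
                                       cfg.recurrence_fraction)

    h = cfg.hash()
    dio.write_segments([s for v in segs.values() for s in v],
                       args.outdir / "segments.tsv", h)
    dio.write_segments([s for v in cnas.values() for s in v],
                       args.outdir / "cnas.tsv", h)
    dio.write_regions_bed(regions, args.outdir / "regions.bed", h)

    print(f"{sum(len(v) for v in segs.values())} segments across "
          f"{len(segs)} patients")
    print(f"{sum(n_cnas)} CNAs after filtering "
          f"(per patient: min {min(n_cnas)}, max {max(n_cnas)})")
    print(f"{len(regions)} recurrent regions "
          f"(>= {cfg.recurrence_fraction:.0%} of patients); "
          f"carriers per region: "
          f"{sorted(r.n_carriers for r in regions)}")


if __name__ == "__main__":
    main()
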