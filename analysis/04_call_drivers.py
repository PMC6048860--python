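#!/usr/bin/env python
"""Network-enrichment driver calling.

Scores each candidate (FGS) gene by the over-representation of its direct
network links to the AGS, z = (d_AF - mu_AF) / sigma_AF under an exact
hypergeometric null, and calls drivers at z > 2 -- common drivers against
the common AGS, patient-specific drivers within each patient.
"""

import argparse
import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from dgscore import io as dio
from dgscore.config import PipelineConfig
from dgscore.pipeline import load_cohort, run_on_cohort


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
    res = run_on_cohort(load_cohort(cfg), cfg, run_survival=False)

    dio.write_drivers(res.driver_calls, args.outdir / "drivers.tsv", cfg.hash())

    print(f"common drivers (z > {cfg.z_threshold:g} vs common AGS): "
          f"{', '.join(d.gene for d in res.common_calls) or 'none'}")
    freq = Counter(d.gene for d in res.patient_calls)
    print(f"{len(res.patient_calls)} patient-specific calls over "
          f"{len(freq)} unique genes; most recurrent: "
          f"{', '.join(f'{g} ({n})' for g, n in freq.most_common(5))}")
    per_patient = Counter(d.scope for d in res.patient_calls)
    if per_patient:
        import numpy as np
        counts = list(per_patient.values())
        print(f"drivers per patient with calls: median "
              f"{float(np.median(counts)):g}, max {max(counts)}")


if __name__ == "__main__":
    main()
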