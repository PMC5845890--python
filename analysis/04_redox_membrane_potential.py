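#!/usr/bin/env python
"""Compartment redox potentials (roGFP) and relative membrane potential (TMRM).

The DTT/H₂O₂-calibrated roGFP trace yields the fraction of oxidized sensor
and, through the Nernst equation, the compartment potential — computed for
the cytosol (pH 7.0) and, with the pH-corrected DTT midpoint, for the
mitochondrial matrix (pH 7.98). The paired-ROI TMRM table gives the
mito/cytosol intensity ratio and each pair's FCCP-response check.
Writes results/redox_summary.csv and results/tmrm_ratios.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from sensortrace import assays as A
from sensortrace import io


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--data-dir", type=Path, default=Path("scratch/data"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    trace = io.read_trace_table(
        args.data_dir / "redox_calibration.csv",
        events_path=args.data_dir / "redox_calibration_events.csv",
    )[0]
    rows = []
    for compartment in ("cytosol", "mitochondria"):
        res = A.redox_assay(trace, compartment=compartment)
        rows.append({
            "compartment": compartment, "ph": res.ph,
            "fraction_oxidized_pct": 100 * res.fraction_oxidized,
            "potential_mV": 1000 * res.potential,
            "f_red": res.calibration["f_red"], "f_ox": res.calibration["f_ox"],
        })
        print(f"{compartment} (pH {res.ph}): "
              f"{100 * res.fraction_oxidized:.1f}% oxidized, "
              f"E' = {1000 * res.potential:.1f} mV")
    pd.DataFrame(rows).to_csv(args.out_dir / "redox_summary.csv", index=False)

    traces = io.read_trace_table(args.data_dir / "tmrm_pairs.csv")
    by_id = {t.trace_id: t for t in traces}
    pairs = [(by_id[m], by_id["cyto" + m[4:]])
             for m in sorted(by_id) if m.startswith("mito")]
    tres = A.tmrm_assay(pairs, fccp_time=60.0)
    pd.DataFrame({
        "pair": range(len(tres.ratios)),
        "mito_mean": [p[0] for p in tres.roi_pairs],
        "cyto_mean": [p[1] for p in tres.roi_pairs],
        "ratio": tres.ratios,
        "fccp_response": tres.fccp_response,
    }).to_csv(args.out_dir / "tmrm_ratios.csv", index=False)
    print(f"TMRM: mean mito/cyto ratio {tres.mean_ratio:.2f} "
          f"(SD {np.std(tres.ratios, ddof=1):.2f}) over {len(pairs)} pairs; "
          f"{100 * np.mean(tres.fccp_response):.0f}% respond to FCCP")


if __name__ == "__main__":
    main()
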