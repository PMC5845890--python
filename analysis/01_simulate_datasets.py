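#!/usr/bin/env python
"""Generate every synthetic dataset the downstream analyses consume.

Writes seeded trace/shift tables (with scenario + seed metadata headers)
under scratch/data/. Ground-truth parameters are stored alongside each
table so later steps can report recovery errors.
"""

import argparse
import json
from pathlib import Path

from sensortrace import io, synthetic as G


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("scratch/data"))
    args = ap.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    truths = {}

    def save(name, traces, truth, events=None, wide=True):
        io.write_trace_table(traces, out / f"{name}.csv",
                             metadata={"scenario": truth.scenario,
                                       "seed": truth.seed}, wide=wide)
        if events:
            io.write_events(events, out / f"{name}_events.csv")
        truths[name] = truth.as_metadata()

    # stimulus-evoked calcium: healthy control vs excitability-impaired
    for label, frac in (("calcium_control", 0.96), ("calcium_impaired", 0.63)):
        traces, truth = G.gen_dff_population(
            n_neurons=100, responder_fraction=frac, seed=args.seed
        )
        save(label, traces, truth, events=[("stimulus", 10.0)])

    tr, truth = G.gen_atp_trace(seed=args.seed)
    save("atp_fccp", [tr], truth, events=tr.events)

    tr, truth = G.gen_redox_trace(fraction_reduced=0.9, seed=args.seed)
    save("redox_calibration", [tr], truth, events=tr.events)

    pairs, truth = G.gen_tmrm_pairs(n_pairs=30, seed=args.seed)
    save("tmrm_pairs", [t for pair in pairs for t in pair], truth,
         events=[("FCCP_on", 60.0)])

    for label, rate in (("network_10dpt", 7.0), ("network_25dpt", 17.0)):
        traces, truth = G.gen_network_raster(
            burst_rate_per_min=rate, seed=args.seed
        )
        meta = {k: v for k, v in truth.as_metadata().items()
                if k != "burst_onsets_true"}
        io.write_trace_table(traces, out / f"{label}.csv", metadata=meta)
        truths[label] = meta

    series, truth = G.gen_titration(kd_true=1.95, seed=args.seed)
    io.write_shift_table(series, out / "titration.csv",
                         metadata={"scenario": truth.scenario,
                                   "seed": truth.seed})
    truths["titration"] = truth.as_metadata()

    (out / "ground_truth.json").write_text(json.dumps(truths, indent=2,
                                                      default=str) + "\n")
    print(f"wrote {len(truths)} datasets under {out}/ (seed {args.seed})")


if __name__ == "__main__":
    main()
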