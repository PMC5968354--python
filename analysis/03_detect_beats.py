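#!/usr/bin/env python
"""Beat detection and contraction metrics against generator ground truth.

Renders a full-length recording at realistic sensor noise, runs the
detector (25-point smoothing, midpoint threshold, run arg-min), derives
BBI / CS / dCS / rCS, and reports recovery accuracy per quantity.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import beatvar as bv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=3)
    ap.add_argument("--n-beats", type=int, default=300)
    ap.add_argument("--noise-sd", type=float, default=0.1)
    args = ap.parse_args()

    cfg = bv.SimConfig(n_beats=args.n_beats, noise_sd=args.noise_sd, seed=args.seed)
    gt = bv.gen_beat_train(cfg)
    trace, _ = bv.gen_gray_trace(gt)
    beats = bv.detect_beats(trace)
    bbi = bv.compute_bbi(beats)
    baselines = bv.compute_baselines(trace, beats)
    cs = bv.compute_cs(beats, baselines)
    rcs = bv.compute_rcs(bv.compute_dcs(beats))

    bbi_err = np.abs(bbi.bbi - gt.intervals_ms)
    cs_err = cs.values - gt.amplitudes
    OUT.mkdir(exist_ok=True)
    pd.DataFrame({
        "beat": np.arange(len(beats)),
        "index": beats.indices,
        "min_value": beats.minima_values,
        "baseline": baselines.values,
        "cs": cs.values,
        "rcs": rcs.values,
        "true_amplitude": gt.amplitudes,
    }).to_csv(OUT / "detection_recovery.csv", index=False)

    print(f"{len(beats)}/{len(gt.indices)} beats detected "
          f"(threshold {beats.threshold_used:.2f} gray)")
    print(f"BBI: max |error| {bbi_err.max():.3f} ms; "
          f"within ±1 ms for {100 * np.mean(bbi_err <= 1):.1f}% of intervals")
    print(f"CS:  bias {cs_err.mean():+.3f} gray, RMS {np.sqrt(np.mean(cs_err**2)):.3f}; "
          f"median CS {np.median(cs.values):.2f} vs true {np.median(gt.amplitudes):.2f}")
    print(f"rCS anchored at {rcs.values[0]:.1f}; identity to beat minima exact: "
          f"{np.allclose(rcs.values, beats.minima_values - beats.minima_values[0])}")


if __name__ == "__main__":
    main()
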