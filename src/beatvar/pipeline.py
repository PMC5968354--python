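"""Whole-study orchestration: series ingest, batch analysis, result tables.

An :class:`ExperimentSet` is a tidy long table of per-beat values — one row
per (experiment, treatment, signal kind, beat) — plus a provenance
manifest.  :func:`run_full_analysis` turns a set into the study's result
tables: group medians per treatment, nonlinear measures per series,
surrogate evaluations (three schemes), and rank correlations of
contraction strength with intervals.  All outputs are long-format CSVs
plus a JSON manifest; re-running with the same manifest reproduces them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import nonlinear_measures as nl
from . import surrogate_stats as ss

__all__ = ["ExperimentSet", "load_supplementary", "run_full_analysis"]

KINDS = ("BBI", "CS", "rCS")
MEASURES = ("SampEn", "D_H")


@dataclass
class ExperimentSet:
    """Per-animal, per-treatment derived series for a whole study.

    ``data`` columns: experiment_id, treatment ("Con"/"ACh"), kind
    ("BBI"/"CS"/"rCS"), beat (0-based), value.  BBI values are in ms,
    CS/rCS in gray units.
    """

    data: pd.DataFrame
    manifest: dict = field(default_factory=dict)

    REQUIRED = ("experiment_id", "treatment", "kind", "beat", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"ExperimentSet table lacks columns {missing}")
        bad_kind = set(self.data["kind"].unique()) - set(KINDS)
        if bad_kind:
            raise ValueError(f"unknown signal kinds {sorted(bad_kind)}")

    @property
    def experiments(self) -> list[str]:
        return sorted(self.data["experiment_id"].unique())

    @property
    def treatments(self) -> list[str]:
        return sorted(self.data["treatment"].unique())

    def incomplete_experiments(self) -> list[str]:
        """Experiments missing one of the treatments (flagged, not dropped)."""
        out = []
        for e in self.experiments:
            present = set(self.data.loc[self.data.experiment_id == e, "treatment"])
            if not {"Con", "ACh"} <= present:
                out.append(e)
        return out

    def series(self, experiment_id: str, treatment: str, kind: str) -> np.ndarray:
        sel = self.data[
            (self.data.experiment_id == experiment_id)
            & (self.data.treatment == treatment)
            & (self.data.kind == kind)
        ].sort_values("beat")
        return sel["value"].to_numpy(dtype=float)

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, manifest: Optional[dict] = None) -> "ExperimentSet":
        return cls(pd.read_csv(path), manifest=manifest or {"source": str(path)})


def load_supplementary(path: str | Path, mapping: Optional[dict] = None) -> ExperimentSet:
    """Read a per-experiment series file (deposited study data or round-trip).

    Two layouts are supported.  Long format needs columns experiment_id,
    treatment, kind, value (and optionally beat).  Wide format needs a
    ``mapping`` of column name -> {"experiment_id", "treatment", "kind"};
    every non-mapped data column is an error that lists the candidates, so
    unknown layouts fail loudly instead of silently dropping series.
    Values are never edited; rows that fail numeric parsing raise with
    their row number.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    cols = set(df.columns)
    if {"experiment_id", "treatment", "kind", "value"} <= cols:
        if "beat" not in cols:
            df["beat"] = df.groupby(["experiment_id", "treatment", "kind"]).cumcount()
        bad = df[pd.to_numeric(df["value"], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value at row(s) {list(bad.index[:5] + 2)}"
            )
        df["value"] = pd.to_numeric(df["value"])
        return ExperimentSet(
            df[list(ExperimentSet.REQUIRED)], manifest={"source": str(path), "layout": "long"}
        )
    if mapping is None:
        raise ValueError(
            f"{path}: not in long format and no column mapping given; "
            f"columns found: {sorted(cols)}"
        )
    unmapped = [c for c in df.columns if c not in mapping]
    if unmapped:
        raise ValueError(
            f"{path}: unmapped columns {unmapped}; map each to "
            "{'experiment_id': ..., 'treatment': 'Con'|'ACh', 'kind': 'BBI'|'CS'|'rCS'}"
        )
    rows = []
    for col, role in mapping.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        series = vals.dropna()
        for beat, v in enumerate(series.to_numpy()):
            rows.append(
                (str(role["experiment_id"]), role["treatment"], role["kind"], beat, float(v))
            )
    out = pd.DataFrame(rows, columns=list(ExperimentSet.REQUIRED))
    return ExperimentSet(out, manifest={"source": str(path), "layout": "wide"})


def _surrogate_sets(
    exp_set: ExperimentSet,
    n_shuffles: int,
    seed: Optional[int],
    m: int,
    r_factor: float,
    k_max: int,
) -> dict:
    """SampEn / D_H surrogate sets per (experiment, treatment, kind).

    One master seed expands into per-series substreams keyed by the sorted
    series order, so any single set is reproducible in isolation.
    """
    keys = [
        (e, t, k)
        for e in exp_set.experiments
        for t in exp_set.treatments
        for k in KINDS
    ]
    root = np.random.SeedSequence(seed)
    out = {}
    for key, child in zip(keys, root.spawn(len(keys))):
        x = exp_set.series(*key)
        if x.size < 10:
            continue
        k_eff = min(k_max, max(2, (x.size - 1) // 2))
        child_seed = int(child.generate_state(1)[0] % (2**31))
        try:
            shuffles = ss.make_surrogates(x, n_shuffles=n_shuffles, seed=child_seed)
            se_orig = nl.sample_entropy(x, m=m, r_factor=r_factor)
            dh_orig = nl.higuchi_dimension(x, k_max=k_eff)[0]
            se_sh = np.array(
                [nl.sample_entropy(s, m=m, r_factor=r_factor) for s in shuffles]
            )
            dh_sh = np.array([nl.higuchi_dimension(s, k_max=k_eff)[0] for s in shuffles])
        except ValueError:
            continue  # degenerate series: flagged in the nonlinear table
        out[key] = {
            "SampEn": ss.SurrogateSet(se_orig, se_sh, "SampEn", seed=child_seed),
            "D_H": ss.SurrogateSet(dh_orig, dh_sh, "D_H", seed=child_seed),
        }
    return out


def run_full_analysis(
    exp_set: ExperimentSet,
    n_shuffles: int = 50,
    seed: Optional[int] = 0,
    m: int = 2,
    r_factor: float = 0.15,
    k_max: int = 30,
    out_dir: Optional[str | Path] = None,
) -> dict:
    """Run the complete study analysis on an :class:`ExperimentSet`.

    Returns a dict of DataFrames: ``medians`` (per-experiment and group
    medians per treatment and kind, with percent change), ``nonlinear``
    (SampEn, D_H with fit r2, DFA alpha per series), ``surrogates``
    (per-series SurrEval-1 p-values and shuffle means), ``surr_tests``
    (SurrEval-2/3 and the experimental Con-vs-ACh median tests), and
    ``spearman`` (CS vs BBI rank correlations).  Degenerate or undefined
    series are flagged in place; the batch never aborts on one series.
    When ``out_dir`` is given all tables are written as CSV plus a JSON
    manifest capturing seeds and parameters.
    """
    per_exp_medians, group_medians = ss.group_summary(exp_set.data)

    nl_rows = []
    for e in exp_set.experiments:
        for t in exp_set.treatments:
            for k in KINDS:
                x = exp_set.series(e, t, k)
                if x.size < 10:
                    continue
                try:
                    res = nl.analyze_series(x, m=m, r_factor=r_factor, k_max=k_max)
                    nl_rows.append(
                        (e, t, k, res.sampen, res.d_h, res.d_h_r2, res.dfa_alpha,
                         "" if res.sampen_defined else "sampen_undefined")
                    )
                except ValueError as exc:
                    nl_rows.append((e, t, k, np.nan, np.nan, np.nan, np.nan, str(exc)))
    nonlinear = pd.DataFrame(
        nl_rows,
        columns=["experiment_id", "treatment", "kind", "sampen", "d_h", "d_h_r2",
                 "dfa_alpha", "flag"],
    )

    sets = _surrogate_sets(exp_set, n_shuffles, seed, m, r_factor, k_max)
    surr_rows = []
    for (e, t, k), both in sets.items():
        for measure in MEASURES:
            s = both[measure]
            finite = np.isfinite(s.shuffled_values)
            try:
                tt = ss.surr_eval_1(
                    ss.SurrogateSet(s.original_value, s.shuffled_values[finite], measure)
                )
                p1, flag = tt.p_value, "" if finite.all() else "undefined_shuffles_dropped"
            except ValueError as exc:
                p1, flag = np.nan, str(exc)
            surr_rows.append(
                (e, t, k, measure, s.original_value,
                 float(np.mean(s.shuffled_values[finite])) if finite.any() else np.nan,
                 p1, flag)
            )
    surrogates = pd.DataFrame(
        surr_rows,
        columns=["experiment_id", "treatment", "kind", "measure", "original",
                 "shuffle_mean", "p_surreval1", "flag"],
    )

    test_rows = []
    exps = exp_set.experiments
    paired = {"Con", "ACh"} <= set(exp_set.treatments)
    for k in KINDS:
        for measure in MEASURES:
            col = {"SampEn": "sampen", "D_H": "d_h"}[measure]
            if paired:
                con_v, ach_v = [], []
                for e in exps:
                    sel = nonlinear[(nonlinear.experiment_id == e) & (nonlinear.kind == k)]
                    c = sel[sel.treatment == "Con"][col]
                    a = sel[sel.treatment == "ACh"][col]
                    if len(c) and len(a) and np.isfinite(c.iloc[0]) and np.isfinite(a.iloc[0]):
                        con_v.append(c.iloc[0])
                        ach_v.append(a.iloc[0])
                if len(con_v) >= 5:
                    r = ss.median_test_paired(con_v, ach_v)
                    test_rows.append((k, measure, "experimental_Con_vs_ACh",
                                      r.median_diff, r.p_value, r.df))
            for t in exp_set.treatments:
                group = [sets[(e, t, k)][measure] for e in exps if (e, t, k) in sets]
                group = [s for s in group if np.isfinite(s.original_value)
                         and np.all(np.isfinite(s.shuffled_values))]
                if len(group) >= 5:
                    r2_ = ss.surr_eval_2(group)
                    test_rows.append((k, measure, f"SurrEval2_{t}",
                                      r2_.median_diff, r2_.p_value, r2_.df))
            if paired:
                con_s, ach_s = [], []
                for e in exps:
                    if (e, "Con", k) in sets and (e, "ACh", k) in sets:
                        sc = sets[(e, "Con", k)][measure]
                        sa = sets[(e, "ACh", k)][measure]
                        if np.isfinite(sc.shuffled_values).all() and np.isfinite(
                            sa.shuffled_values
                        ).all():
                            con_s.append(sc)
                            ach_s.append(sa)
                if len(con_s) >= 5 and len(con_s) == len(ach_s):
                    r3 = ss.surr_eval_3(con_s, ach_s)
                    test_rows.append((k, measure, "SurrEval3_shufCon_vs_shufACh",
                                      r3.median_diff, r3.p_value, r3.df))
    surr_tests = pd.DataFrame(
        test_rows, columns=["kind", "measure", "comparison", "median_diff", "p", "df"]
    )

    sp_rows = []
    for e in exps:
        for t in exp_set.treatments:
            cs = exp_set.series(e, t, "CS")
            bbi = exp_set.series(e, t, "BBI")
            if cs.size >= 4 and bbi.size >= 3:
                n = min(cs.size - 1, bbi.size)
                rs, df_ = ss.spearman_rs(cs[1 : n + 1], bbi[:n])
                sp_rows.append((e, t, rs, df_))
    spearman = pd.DataFrame(sp_rows, columns=["experiment_id", "treatment", "rs", "df"])

    results = {
        "medians": group_medians,
        "per_experiment_medians": per_exp_medians,
        "nonlinear": nonlinear,
        "surrogates": surrogates,
        "surr_tests": surr_tests,
        "spearman": spearman,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in results.items():
            df.to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "input_manifest": exp_set.manifest,
            "params": {"n_shuffles": n_shuffles, "seed": seed, "m": m,
                       "r_factor": r_factor, "k_max": k_max},
            "n_experiments": len(exps),
            "incomplete_experiments": exp_set.incomplete_experiments(),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
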