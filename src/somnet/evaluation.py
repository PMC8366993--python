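"""Cohen's kappa scoring, the three-experiment validation harness, and the
cross-database aggregation arithmetic.

Experiment 1 measures local generalization: each site trains its own model
and is scored on its held-out test recordings.  Experiment 2 is the
cross-prediction matrix: every local model predicts every complete site
dataset (the diagonal is biased, since the model saw most of that data in
training).  Experiment 3 predicts each site with a majority-vote ensemble
of the other sites' models.  Site-level kappas pool epochs across
recordings into a single confusion matrix.

The package also ships the published six-database benchmark tables from
the study this design replicates (local kappas, the full cross-prediction
matrix, and the ensemble kappas), so the aggregation arithmetic can be
checked against the printed summary values.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ensemble import EnsembleSpec, ensemble_predict
from .model import ModelConfig, RecordingPatterns, SleepStager
from .psg_io import AASM_STAGES, ValidationError
from .training import SplitSpec, TrainSettings, effective_iterations, split_dataset, train_model

N_STAGES = len(AASM_STAGES)


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class KappaReport:
    kappa: float
    confusion: np.ndarray  # (5, 5), rows = reference, cols = prediction
    n_epochs_scored: int
    n_excluded_unknown: int


def cohens_kappa(reference: Sequence[str], prediction: Sequence[str]) -> KappaReport:
    """Unweighted Cohen's kappa over the five AASM stages.

    kappa = (p_o - p_e) / (1 - p_e), with p_o the observed agreement
    fraction and p_e the chance agreement from the confusion-matrix
    marginals.  Epochs where either sequence is UNKNOWN are excluded
    pairwise (and counted) before scoring.
    """
    if len(reference) != len(prediction):
        raise ValidationError("reference and prediction differ in length")
    idx = {s: i for i, s in enumerate(AASM_STAGES)}
    conf = np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    excluded = 0
    for r, p in zip(reference, prediction):
        if r in idx and p in idx:
            conf[idx[r], idx[p]] += 1
        else:
            excluded += 1
    n = int(conf.sum())
    if n == 0:
        raise ValidationError("no scored epoch pairs after UNKNOWN exclusion")
    p_o = np.trace(conf) / n
    p_e = float(conf.sum(axis=1) @ conf.sum(axis=0)) / n**2
    kappa = 1.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    return KappaReport(
        kappa=float(kappa), confusion=conf, n_epochs_scored=n,
        n_excluded_unknown=excluded,
    )


def pooled_kappa(
    refs: Sequence[Sequence[str]], preds: Sequence[Sequence[str]]
) -> KappaReport:
    """Kappa over epochs pooled across several recordings."""
    flat_r = [s for seq in refs for s in seq]
    flat_p = [s for seq in preds for s in seq]
    return cohens_kappa(flat_r, flat_p)


# ---------------------------------------------------------------------------
# Cross-prediction matrix and aggregation arithmetic
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class CrossPredictionMatrix:
    """values[i, j] = kappa of the model trained on site i predicting the
    complete dataset of site j; the diagonal is a biased (seen-data)
    prediction and is excluded from external statistics."""

    values: np.ndarray
    origin_ids: list[str]
    diagonal_biased: bool = True

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        k = len(self.origin_ids)
        if self.values.shape != (k, k) or k < 2:
            raise ValidationError("cross-prediction matrix must be KxK, K >= 2")

    def external_column(self, j) -> np.ndarray:
        """Off-diagonal kappas of all external models predicting dataset j."""
        if isinstance(j, str):
            j = self.origin_ids.index(j)
        mask = np.ones(len(self.origin_ids), dtype=bool)
        mask[j] = False
        return self.values[mask, j]


def external_stats(values: np.ndarray) -> tuple[float, float, float]:
    """(range_min, range_max, average) over external kappas of one dataset."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValidationError("no external values")
    return float(v.min()), float(v.max()), float(v.mean())


def round_half_away(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (matches printed tables)."""
    f = 10.0**decimals
    return np.sign(x) * np.floor(abs(x) * f + 0.5) / f


def global_aggregate(
    local: Sequence[float],
    external_avg: Sequence[float],
    ensemble: Sequence[float],
) -> dict[str, float]:
    """Across-dataset means and pairwise differences for one variant.

    I = mean local test kappa, II = mean external average kappa,
    III = mean ensemble kappa.  Differences are computed from the unrounded
    means (II - I, III - I, III - II; the first two are negative whenever
    external prediction degrades performance).
    """
    if not (len(local) == len(external_avg) == len(ensemble)):
        raise ValidationError("aggregation inputs must cover the same datasets")
    I = float(np.mean(local))
    II = float(np.mean(external_avg))
    III = float(np.mean(ensemble))
    return {
        "I": I, "II": II, "III": III,
        "I_vs_II": II - I, "I_vs_III": III - I, "II_vs_III": III - II,
    }


# ---------------------------------------------------------------------------
# Experiments 1-3
# ---------------------------------------------------------------------------

def _site_reference(recs: list[RecordingPatterns]) -> list[list[str]]:
    return [r.stages for r in recs]


def _predict_site(model: SleepStager, recs: list[RecordingPatterns]):
    """Per-recording (stages, posteriors) for a whole site."""
    out = []
    for rec in recs:
        hyp, proba = model.predict_recording(rec)
        out.append((hyp.stages, proba))
    return out


def run_experiment1(
    sites: dict[str, list[RecordingPatterns]],
    cfg: ModelConfig,
    seed: int,
    settings: Optional[TrainSettings] = None,
    min_recordings: int = 5,
):
    """Train one local model per site; report TR/VAL/TS kappas.

    Returns (DataFrame with one row per site, dict site -> trained model,
    dict site -> SplitSpec).
    """
    rows, models, splits = [], {}, {}
    for si, (name, recs) in enumerate(sites.items()):
        split = split_dataset(
            [r.rec_id for r in recs], seed=seed + si, min_recordings=min_recordings
        )
        splits[name] = split
        by_id = {r.rec_id: r for r in recs}
        tr = [by_id[i] for i in split.train_ids]
        val = [by_id[i] for i in split.val_ids]
        ts = [by_id[i] for i in split.test_ids]
        model = SleepStager(cfg, seed=seed)
        state = train_model(model, tr, val, seed=seed, settings=settings)
        kappas = {}
        for part, part_recs in (("tr", tr), ("val", val), ("ts", ts)):
            preds = [stages for stages, _ in _predict_site(model, part_recs)]
            kappas[part] = pooled_kappa(_site_reference(part_recs), preds).kappa
        rows.append(
            {
                "dataset": name,
                "variant": cfg.name,
                "iterations": effective_iterations(state),
                "kappa_tr": kappas["tr"],
                "kappa_val": kappas["val"],
                "kappa_ts": kappas["ts"],
            }
        )
        models[name] = model
    return pd.DataFrame(rows), models, splits


def run_experiment2(
    models: dict[str, SleepStager], sites: dict[str, list[RecordingPatterns]]
):
    """Cross-prediction: every local model scores every complete dataset.

    Returns (CrossPredictionMatrix, posterior cache indexed by
    (origin, dataset) holding per-recording posterior matrices) so that
    Experiment 3 can reuse the member predictions.
    """
    names = list(sites.keys())
    missing = [n for n in names if n not in models]
    if missing:
        raise ValidationError(f"missing local models for: {', '.join(missing)}")
    variants = {m.cfg.name for m in models.values()}
    if len(variants) != 1:
        raise ValidationError("cross-prediction requires one shared variant")
    K = len(names)
    values = np.zeros((K, K))
    cache: dict[tuple[str, str], list[np.ndarray]] = {}
    for i, origin in enumerate(names):
        for j, target in enumerate(names):
            preds = _predict_site(models[origin], sites[target])
            cache[(origin, target)] = [proba for _, proba in preds]
            values[i, j] = pooled_kappa(
                _site_reference(sites[target]), [st for st, _ in preds]
            ).kappa
    return CrossPredictionMatrix(values=values, origin_ids=names), cache


def run_experiment3(
    models: dict[str, SleepStager],
    sites: dict[str, list[RecordingPatterns]],
    posterior_cache: Optional[dict] = None,
) -> dict[str, float]:
    """Ensemble prediction of each dataset by all *other* sites' models."""
    names = list(sites.keys())
    out = {}
    for target in names:
        member_names = [n for n in names if n != target]
        spec = EnsembleSpec(
            members=[(models[n], n) for n in member_names],
            excluded_origin=target,
        )
        preds = []
        for ri, rec in enumerate(sites[target]):
            member_posts = None
            if posterior_cache is not None:
                member_posts = [posterior_cache[(n, target)][ri] for n in member_names]
            preds.append(ensemble_predict(spec, rec, member_posts).stages)
        out[target] = pooled_kappa(_site_reference(sites[target]), preds).kappa
    return out


# ---------------------------------------------------------------------------
# Published six-database benchmark tables
# ---------------------------------------------------------------------------

def _read_table(name: str) -> pd.DataFrame:
    with resources.files("somnet").joinpath("data", name).open() as fh:
        return pd.read_csv(fh)


def load_published_benchmark() -> dict[str, pd.DataFrame]:
    """The published six-database kappa tables shipped with the package.

    ``local``: per-site, per-variant training iterations and TR/VAL/TS
    kappas.  ``cross``: the full model-origin x predicted-dataset kappa
    matrix per variant.  ``comparison``: per-site local kappa, external
    range/average, and ensemble kappa.  ``global``: across-site averages
    and their differences per variant.
    """
    return {
        "local": _read_table("published_local.csv"),
        "cross": _read_table("published_cross.csv"),
        "comparison": _read_table("published_comparison.csv"),
        "global": _read_table("published_global.csv"),
    }


def reproduce_published_aggregation(tables: Optional[dict] = None):
    """Recompute the published summary tables from their inputs.

    The external range/average columns are recomputed from the
    cross-prediction matrix (diagonal excluded); the global table is
    recomputed from per-site local, external-average, and ensemble columns.
    Returns (comparison_df, global_df) with unrounded computed values.
    """
    t = tables or load_published_benchmark()
    cross, local, comp = t["cross"], t["local"], t["comparison"]
    datasets = list(dict.fromkeys(cross["dataset"]))
    variants = list(dict.fromkeys(cross["variant"]))

    comp_rows = []
    for ds in datasets:
        for v in variants:
            row = cross[(cross["dataset"] == ds) & (cross["variant"] == v)].iloc[0]
            ext = np.array([row[f"M_{o}"] for o in datasets if o != ds], dtype=float)
            mn, mx, avg = external_stats(ext)
            loc = float(
                local[(local["dataset"] == ds) & (local["variant"] == v)]
                ["kappa_ts"].iloc[0]
            )
            ens = float(
                comp[(comp["dataset"] == ds) & (comp["variant"] == v)]
                ["ensemble"].iloc[0]
            )
            comp_rows.append(
                {
                    "dataset": ds, "variant": v, "local": loc,
                    "ext_min": mn, "ext_max": mx, "ext_avg": avg,
                    "ensemble": ens,
                }
            )
    comp_df = pd.DataFrame(comp_rows)

    glob_rows = []
    for v in variants:
        sub = comp.loc[comp["variant"] == v].set_index("dataset").loc[datasets]
        agg = global_aggregate(
            sub["local"].to_numpy(float),
            sub["ext_avg"].to_numpy(float),
            sub["ensemble"].to_numpy(float),
        )
        glob_rows.append(
            {
                "variant": v,
                "local_avg": agg["I"], "external_avg": agg["II"],
                "ensemble_avg": agg["III"],
                "i_vs_ii": agg["I_vs_II"], "i_vs_iii": agg["I_vs_III"],
                "ii_vs_iii": agg["II_vs_III"],
            }
        )
    return comp_df, pd.DataFrame(glob_rows)
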