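"""End-to-end analysis: dataset -> connectivity -> networks -> statistics.

``run_full_analysis`` executes the whole chain on a trial-structured
dataset: common average reference, band decomposition, PLI (or wPLI)
connectivity, hemispheric network construction, topological metrics over
the sparsity range, AUC aggregation, within-subject averaging, and the
hemisphere-comparison statistics (paired tests, asymmetry scores,
FDR-corrected nodal comparisons).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from . import connectivity as conn
from . import network as net
from . import preprocess as pp
from . import stats as st
from .exceptions import ValidationError
from .montage import Montage, deap_montage

logger = logging.getLogger(__name__)

GLOBAL_METRICS = ("Cp", "Lp", "Eg", "Eloc", "sigma")


@dataclass
class AnalysisConfig:
    """All knobs of the analysis pipeline.

    Defaults follow the standard protocol: four bands, PLI edges,
    sparsity 5-40% in 1% steps, binary metrics, 100-surrogate null for
    sigma, strict ">5" categorisation, and the 14-pair FDR family.
    """

    bands: tuple[str, ...] = ("theta", "alpha", "beta", "gamma")
    categories: tuple[str, ...] = pp.CATEGORIES
    method: str = "pli"
    trim: int = conn.DEFAULT_TRIM
    reference: str = "common_average"     # or "none"
    rating_boundary: str = "gt"           # "high" means > 5 ("ge": >= 5)
    rating_threshold: float = 5.0
    baseline_seconds: float = 0.0
    threshold_lo: float = 5.0             # percent
    threshold_hi: float = 40.0
    threshold_step: float = 1.0
    metrics: tuple[str, ...] = GLOBAL_METRICS
    include_nodal: bool = True
    weighted: bool = False
    n_null: int = 100
    null_swap_factor: int = 10
    fdr_q: float = 0.05
    correct_global: bool = False   # FDR-correct global tests too
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("pli", "wpli"):
            raise ValidationError(f"unknown connectivity method {self.method!r}")
        if self.reference not in ("common_average", "none"):
            raise ValidationError(f"unknown reference {self.reference!r}")
        if not (0 < self.threshold_lo <= self.threshold_hi <= 100):
            raise ValidationError("need 0 < threshold_lo <= threshold_hi <= 100")
        if self.threshold_step <= 0:
            raise ValidationError("threshold_step must be positive")
        unknown = set(self.metrics) - set(GLOBAL_METRICS)
        if unknown:
            raise ValidationError(f"unknown metrics {sorted(unknown)}")
        if self.weighted and "sigma" in self.metrics:
            raise ValidationError(
                "sigma uses a binary rewiring null; drop it from metrics "
                "when weighted=True")

    @property
    def thresholds_percent(self) -> np.ndarray:
        return np.arange(self.threshold_lo,
                         self.threshold_hi + self.threshold_step / 2,
                         self.threshold_step)

    @property
    def thresholds(self) -> np.ndarray:
        """Threshold axis as fractions, used for the AUC integral."""
        return self.thresholds_percent / 100.0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class AnalysisResult:
    """All result surfaces of one analysis run."""

    global_tests: pd.DataFrame
    asymmetry_global: pd.DataFrame
    nodal_tests: pd.DataFrame
    asymmetry_nodal: pd.DataFrame
    subject_auc: pd.DataFrame        # per subject x category x band x hemisphere
    subject_nodal_auc: pd.DataFrame
    counts: pd.DataFrame             # trials per category after exclusion
    excluded: dict[int, list[str]]

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "global_tests": self.global_tests,
            "asymmetry_global": self.asymmetry_global,
            "nodal_tests": self.nodal_tests,
            "asymmetry_nodal": self.asymmetry_nodal,
            "subject_auc": self.subject_auc,
            "subject_nodal_auc": self.subject_nodal_auc,
            "category_counts": self.counts,
        }


# ---------------------------------------------------------------------------
# Per-trial metric curves
# ---------------------------------------------------------------------------

def threshold_metric_curves(raw: np.ndarray, config: AnalysisConfig,
                            rng: np.random.Generator | None = None,
                            ) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
    """Metric value per sparsity threshold for one raw weighted matrix.

    Returns (global metric curves, nodal efficiency curve of shape
    (n_thresholds, n_nodes) or None).  The edge ranking is computed once
    and adjacencies grown incrementally as the threshold rises.
    """
    n = raw.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = raw[iu, ju]
    order = np.lexsort((ju, iu, -w))
    thresholds = config.thresholds_percent
    ks = [net.edge_count(s, n) for s in thresholds]

    want = set(config.metrics)
    need_dist = bool(want & {"Lp", "Eg"})
    curves = {m: np.empty(len(thresholds)) for m in want}
    nodal = (np.empty((len(thresholds), n)) if config.include_nodal else None)

    adj = np.zeros((n, n))
    prev = 0
    for t_i, k in enumerate(ks):
        add = order[prev:k]
        if config.weighted:
            adj[iu[add], ju[add]] = w[add]
            adj[ju[add], iu[add]] = w[add]
        else:
            adj[iu[add], ju[add]] = 1.0
            adj[ju[add], iu[add]] = 1.0
        prev = max(prev, k)
        if config.weighted:
            gm = net.weighted_global_metrics(adj)
            if "Cp" in want:
                curves["Cp"][t_i] = gm.cp
            if "Lp" in want:
                curves["Lp"][t_i] = gm.lp
            if "Eg" in want:
                curves["Eg"][t_i] = gm.eg
            if "Eloc" in want:
                curves["Eloc"][t_i] = gm.eloc
            if nodal is not None:
                nodal[t_i] = net.weighted_nodal_efficiency(adj)
            continue
        if "Cp" in want:
            curves["Cp"][t_i] = net.clustering_coefficient(adj)
        if need_dist or nodal is not None:
            eff = net._efficiency_matrix(adj)
            if "Eg" in want:
                curves["Eg"][t_i] = eff.sum() / (n * (n - 1))
            if nodal is not None:
                nodal[t_i] = eff.sum(axis=1) / (n - 1)
            if "Lp" in want:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", net.DisconnectedGraphWarning)
                    curves["Lp"][t_i] = net.characteristic_path_length(adj)
        if "Eloc" in want:
            curves["Eloc"][t_i] = net.local_efficiency(adj)
        if "sigma" in want:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                curves["sigma"][t_i], _, _ = net.small_world_sigma(
                    adj, n_null=config.n_null, rng=rng,
                    swap_factor=config.null_swap_factor)
    return curves, nodal


def _connectivity_cache_key(config: AnalysisConfig, band: str, fs: float) -> str:
    """Content hash of the config sections the connectivity stage depends on."""
    import hashlib
    import json
    payload = json.dumps({
        "band": band, "fs": fs, "method": config.method, "trim": config.trim,
        "reference": config.reference, "baseline_seconds": config.baseline_seconds,
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _compute_band_matrices(arr: np.ndarray, band: str, fs: float,
                           config: AnalysisConfig) -> np.ndarray:
    filt = pp.bandpass_array(arr, band, fs)
    z = conn.analytic_batch(filt, config.trim)
    if config.method == "pli":
        return conn.pli_matrix_batch(z)
    return conn.wpli_matrix_batch(z)


def trial_auc_records(dataset: pp.EEGDataset, config: AnalysisConfig,
                      montage: Montage | None = None,
                      cache_dir=None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame,
                                 dict[int, list[str]]]:
    """Per-trial AUC of every metric for both hemispheres.

    Returns (global AUC records, nodal AUC records, category counts,
    excluded subjects).  With ``cache_dir`` set, per-(subject, band)
    connectivity matrices are reused from disk when the connectivity
    settings match, and written there otherwise.
    """
    montage = montage or deap_montage()
    categorized = pp.categorize_ratings(
        dataset.ratings, config.rating_threshold, config.rating_boundary)
    ratings, removed = pp.exclude_incomplete_subjects(categorized)
    counts = (ratings["category"].value_counts()
              .reindex(pp.CATEGORIES, fill_value=0)
              .rename_axis("category").reset_index(name="n_trials"))
    logger.info("trials per category after exclusion: %s",
                dict(zip(counts["category"], counts["n_trials"])))

    order = montage.resolve(dataset.channels)
    hemi_ix = {side: [order[i] for i in
                      montage.indices(montage.hemisphere_channels(side))]
               for side in ("left", "right")}
    node_names = {side: montage.hemisphere_channels(side)
                  for side in ("left", "right")}
    thresholds = config.thresholds
    band_list = list(config.bands)

    rows, nodal_rows = [], []
    subjects = [s for s in sorted(dataset.data) if s in set(ratings["subject"])]
    for s in subjects:
        sub = ratings[(ratings["subject"] == s)
                      & ratings["category"].isin(config.categories)]
        if sub.empty:
            continue
        trial_ids = sub["trial"].to_numpy()
        cats = sub["category"].to_numpy()
        arr = dataset.data[s][trial_ids]
        arr = pp.drop_baseline(arr, dataset.fs, config.baseline_seconds)
        if config.reference == "common_average":
            arr = pp.car_array(arr)
        for b_i, band in enumerate(band_list):
            mats = None
            cache_file = None
            if cache_dir is not None:
                from pathlib import Path
                key = _connectivity_cache_key(config, band, dataset.fs)
                cache_file = (Path(cache_dir)
                              / f"conn_s{int(s):02d}_{band}_{key}.npz")
                if cache_file.exists():
                    with np.load(cache_file) as npz:
                        cached_ids = npz["trial_ids"]
                        if set(trial_ids) <= set(cached_ids):
                            pos = {t: i for i, t in enumerate(cached_ids)}
                            mats = npz["matrices"][[pos[t] for t in trial_ids]]
                            logger.info("connectivity cache hit: %s", cache_file)
            if mats is None:
                mats = _compute_band_matrices(arr, band, dataset.fs, config)
                if cache_file is not None:
                    cache_file.parent.mkdir(parents=True, exist_ok=True)
                    np.savez_compressed(cache_file, trial_ids=trial_ids,
                                        matrices=mats)
            for t_i, (trial_id, cat) in enumerate(zip(trial_ids, cats)):
                for h_i, side in enumerate(("left", "right")):
                    ix = hemi_ix[side]
                    raw = mats[t_i][np.ix_(ix, ix)]
                    np.fill_diagonal(raw, 0.0)
                    rng = np.random.Generator(np.random.PCG64(
                        np.random.SeedSequence(
                            config.seed,
                            spawn_key=(int(s), int(trial_id), b_i, h_i))))
                    curves, nodal = threshold_metric_curves(raw, config, rng)
                    for metric, vals in curves.items():
                        rows.append((s, int(trial_id), cat, band, side, metric,
                                     st.auc(thresholds, vals)))
                    if nodal is not None:
                        nodal_auc = st.auc(thresholds, nodal)
                        for node, value in zip(node_names[side], nodal_auc):
                            nodal_rows.append((s, int(trial_id), cat, band,
                                               side, node, float(value)))
    cols = ["subject", "trial", "category", "band", "hemisphere"]
    records = pd.DataFrame(rows, columns=cols + ["metric", "auc"])
    nodal_records = pd.DataFrame(nodal_rows, columns=cols + ["node", "auc"])
    return records, nodal_records, counts, removed


# ---------------------------------------------------------------------------
# Statistics over subjects
# ---------------------------------------------------------------------------

def _pivot_hemispheres(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    wide = df.pivot_table(index=keys, columns="hemisphere", values="auc",
                          aggfunc="first").reset_index()
    return wide.dropna(subset=["left", "right"])


def run_full_analysis(dataset: pp.EEGDataset, config: AnalysisConfig,
                      montage: Montage | None = None,
                      cache_dir=None) -> AnalysisResult:
    """Execute the complete hemispheric-asymmetry analysis."""
    montage = montage or deap_montage()
    records, nodal_records, counts, removed = trial_auc_records(
        dataset, config, montage, cache_dir=cache_dir)

    subj = st.subject_average(records)
    subj_nodal = st.subject_average(
        nodal_records, keys=("subject", "category", "band", "hemisphere", "node"))

    pair_of = {left: f"{left}-{right}"
               for left, right in montage.homologous_pairs}
    pair_of.update({right: f"{left}-{right}"
                    for left, right in montage.homologous_pairs})

    global_rows, as_rows = [], []
    wide = _pivot_hemispheres(subj, ["band", "category", "metric", "subject"])
    for (band, cat, metric), grp in wide.groupby(["band", "category", "metric"],
                                                 sort=True):
        left = grp["left"].to_numpy()
        right = grp["right"].to_numpy()
        if left.size < 3:
            logger.warning("skipping %s/%s/%s: only %d subjects",
                           band, cat, metric, left.size)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t, p = st.paired_hemisphere_test(left, right)
            diff = left - right
            if np.ptp(diff) > 0:
                _, norm_p, norm_ok = st.normality_check(diff)
            else:
                norm_p, norm_ok = float("nan"), False
        global_rows.append({
            "band": band, "category": cat, "metric": metric,
            "n_subjects": left.size,
            "mean_left": left.mean(), "mean_right": right.mean(),
            "t": t, "p": p, "normality_p": norm_p, "normality_pass": norm_ok,
        })
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            as_vals = st.asymmetry_score(left, right)
            as_vals = as_vals[np.isfinite(as_vals)]
            if as_vals.size >= 3:
                t_as, p_as = st.one_sample_as_test(as_vals)
            else:
                t_as, p_as = float("nan"), float("nan")
        as_rows.append({
            "band": band, "category": cat, "metric": metric,
            "n_subjects": int(as_vals.size), "mean_as": as_vals.mean()
            if as_vals.size else float("nan"), "t": t_as, "p": p_as,
        })

    nodal_rows, as_nodal_rows = [], []
    if not subj_nodal.empty:
        lateral = subj_nodal[subj_nodal["node"].map(pair_of).notna()].copy()
        lateral["pair"] = lateral["node"].map(pair_of)
        widep = lateral.pivot_table(
            index=["band", "category", "pair", "subject"],
            columns="hemisphere", values="auc", aggfunc="first").reset_index()
        widep = widep.dropna(subset=["left", "right"])
        for (band, cat), fam in widep.groupby(["band", "category"], sort=True):
            fam_rows, fam_as_rows = [], []
            for pair, grp in fam.groupby("pair", sort=True):
                left = grp["left"].to_numpy()
                right = grp["right"].to_numpy()
                if left.size < 3:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    t, p = st.paired_hemisphere_test(left, right)
                    as_vals = st.asymmetry_score(left, right)
                    as_vals = as_vals[np.isfinite(as_vals)]
                    t_as, p_as = (st.one_sample_as_test(as_vals)
                                  if as_vals.size >= 3
                                  else (float("nan"), float("nan")))
                fam_rows.append({
                    "band": band, "category": cat, "pair": pair,
                    "n_subjects": left.size, "mean_left": left.mean(),
                    "mean_right": right.mean(), "t": t, "p": p,
                })
                fam_as_rows.append({
                    "band": band, "category": cat, "pair": pair,
                    "n_subjects": int(as_vals.size),
                    "mean_as": as_vals.mean() if as_vals.size else float("nan"),
                    "t": t_as, "p": p_as,
                })
            for rows_, src in ((nodal_rows, fam_rows),
                               (as_nodal_rows, fam_as_rows)):
                if not src:
                    continue
                reject, adjusted = st.fdr_correct(
                    [r["p"] for r in src], q=config.fdr_q)
                for r, rej, adj in zip(src, reject, adjusted):
                    r["p_fdr"] = adj
                    r["significant"] = bool(rej)
                    rows_.append(r)

    global_df = pd.DataFrame(global_rows)
    as_df = pd.DataFrame(as_rows)
    if config.correct_global and not global_df.empty:
        # optional BH correction of the global tests, per band x category
        for df in (global_df, as_df):
            df["p_fdr"] = np.nan
            df["significant"] = False
            for _, idx in df.groupby(["band", "category"]).groups.items():
                reject, adjusted = st.fdr_correct(df.loc[idx, "p"],
                                                  q=config.fdr_q)
                df.loc[idx, "p_fdr"] = adjusted
                df.loc[idx, "significant"] = reject

    return AnalysisResult(
        global_tests=global_df,
        asymmetry_global=as_df,
        nodal_tests=pd.DataFrame(nodal_rows),
        asymmetry_nodal=pd.DataFrame(as_nodal_rows),
        subject_auc=subj,
        subject_nodal_auc=subj_nodal,
        counts=counts,
        excluded=removed,
    )


__all__ = ["AnalysisConfig", "AnalysisResult", "GLOBAL_METRICS",
           "threshold_metric_curves", "trial_auc_records",
           "run_full_analysis"]
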