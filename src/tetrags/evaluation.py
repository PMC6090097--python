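"""Cross-validation, across-population prediction and the experiment grid.

Accuracy is the Pearson correlation r(GEBV : y) between predicted breeding
values and observed (environment-adjusted) phenotypes.  Bias is the OLS
slope beta of y regressed on the GEBVs: beta = 1 means no bias, beta > 1
means the prediction scale is deflated (spread of the GEBVs too small),
beta < 1 inflated.  Within-population accuracy uses repeated k-fold
cross-validation; per-individual GEBVs are averaged over the repeats before
the headline r and beta are computed, with per-repeat statistics retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixed import profile_reml
from .gblup import SolverConfig, _check_psd, fit_gblup
from .genotypes import (AlleleFrequencyMatrix, random_marker_sets,
                        stringent_marker_set)
from .grm import GenomicRelationshipMatrix, grm_from_af

__all__ = [
    "CVScheme",
    "PredictionEvaluation",
    "prediction_correlation",
    "prediction_bias",
    "kfold_cv",
    "loocv",
    "cross_population",
    "combined_cv",
    "run_experiment_grid",
    "load_config",
]


@dataclass
class CVScheme:
    """k-fold or leave-one-out cross-validation settings."""

    k: int = 5
    n_repeats: int = 50
    seed: int = 0
    mode: str = "kfold"

    def __post_init__(self):
        if self.mode not in ("kfold", "loo"):
            raise ValueError("mode must be 'kfold' or 'loo'")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class PredictionEvaluation:
    """Accuracy and bias of one prediction experiment."""

    ids: list[str]
    gebv: pd.Series               # per-individual mean GEBV over repeats
    y: pd.Series
    r: float
    beta: float
    per_repeat: pd.DataFrame      # columns repeat, r, beta
    metadata: dict = field(default_factory=dict)


def prediction_correlation(gebv, y) -> float:
    """Pearson correlation r(GEBV : y)."""
    g = np.asarray(gebv, float)
    yv = np.asarray(y, float)
    if g.size != yv.size or g.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if g.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance in gebv or y")
    return float(np.corrcoef(g, yv)[0, 1])


def prediction_bias(gebv, y) -> float:
    """OLS slope of y on GEBV (beta = 1: unbiased; > 1: deflated scale)."""
    g = np.asarray(gebv, float)
    yv = np.asarray(y, float)
    if g.size != yv.size or g.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    vg = g.var(ddof=1)
    if vg == 0:
        raise ValueError("zero variance in gebv")
    return float(np.cov(yv, g, ddof=1)[0, 1] / vg)


def _predict_block(yv: np.ndarray, Gm: np.ndarray, tr: np.ndarray,
                   te: np.ndarray, solver: SolverConfig) -> np.ndarray:
    """GEBVs for te given phenotypes of tr, on a PSD-checked G matrix."""
    if tr.size < 2:
        raise ValueError("fold leaves fewer than 2 training individuals")
    if solver.method == "REML":
        Gtt = Gm[np.ix_(tr, tr)]
        fit = profile_reml(yv[tr], np.ones((tr.size, 1)), Gtt,
                           delta=solver.var_ratio)
        if fit.sigma2_g == 0.0 or not np.isfinite(fit.delta):
            return np.zeros(te.size)
        A = Gtt + fit.delta * np.eye(tr.size)
        return Gm[np.ix_(te, tr)] @ np.linalg.solve(A, yv[tr] - fit.beta[0])
    ids = [str(i) for i in range(Gm.shape[0])]
    sub = GenomicRelationshipMatrix(ids, Gm, np.nan)
    fit = fit_gblup(pd.Series(yv[tr], index=[ids[i] for i in tr]), sub, solver)
    return fit.gebv.to_numpy()[te]


def _repeat_rng(seed: int, repeat: int) -> np.random.Generator:
    # counter-based seed derivation: any repeat can be re-run in isolation
    return np.random.default_rng(np.random.SeedSequence((seed, repeat)))


def _kfold_gebv_matrix(yv: np.ndarray, Gm: np.ndarray,
                       scheme: CVScheme, solver: SolverConfig) -> np.ndarray:
    """(n_repeats, n) out-of-fold GEBVs; each individual predicted exactly
    once per repeat, never by a model that saw its own phenotype."""
    n = yv.size
    k = n if scheme.mode == "loo" else scheme.k
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    n_repeats = 1 if scheme.mode == "loo" else scheme.n_repeats
    out = np.empty((n_repeats, n))
    for rep in range(n_repeats):
        rng = _repeat_rng(scheme.seed, rep)
        perm = rng.permutation(n)
        for fold in np.array_split(perm, k):
            tr = np.setdiff1d(np.arange(n), fold)
            out[rep, fold] = _predict_block(yv, Gm, tr, fold, solver)
    return out


def _evaluate(ids, gebv_matrix: np.ndarray, yv: np.ndarray,
              metadata: dict) -> PredictionEvaluation:
    mean_gebv = gebv_matrix.mean(axis=0)
    rows = [{"repeat": rep,
             "r": prediction_correlation(gebv_matrix[rep], yv),
             "beta": prediction_bias(gebv_matrix[rep], yv)}
            for rep in range(gebv_matrix.shape[0])]
    return PredictionEvaluation(
        ids=list(ids), gebv=pd.Series(mean_gebv, index=list(ids)),
        y=pd.Series(yv, index=list(ids)),
        r=prediction_correlation(mean_gebv, yv),
        beta=prediction_bias(mean_gebv, yv),
        per_repeat=pd.DataFrame(rows), metadata=metadata)


def kfold_cv(y: pd.Series, G: GenomicRelationshipMatrix,
             scheme: CVScheme | None = None,
             solver: SolverConfig | None = None) -> PredictionEvaluation:
    """Repeated k-fold cross-validation within one population."""
    scheme = scheme or CVScheme()
    solver = solver or SolverConfig()
    ids = list(y.index)
    Gm = _check_psd(G.submatrix(ids).matrix)
    yv = y.to_numpy(float)
    gebvs = _kfold_gebv_matrix(yv, Gm, scheme, solver)
    return _evaluate(ids, gebvs, yv,
                     {"experiment": "kfold", "k": scheme.k,
                      "n_repeats": gebvs.shape[0], "n": len(ids)})


def loocv(y: pd.Series, G: GenomicRelationshipMatrix,
          solver: SolverConfig | None = None) -> PredictionEvaluation:
    """Leave-one-out cross-validation (single pass, no repeats)."""
    if y.size < 3:
        raise ValueError("leave-one-out needs n >= 3")
    scheme = CVScheme(k=2, n_repeats=1, mode="loo")
    out = kfold_cv(y, G, scheme, solver)
    out.metadata["experiment"] = "loocv"
    return out


def cross_population(y_train: pd.Series, y_test: pd.Series,
                     G: GenomicRelationshipMatrix,
                     solver: SolverConfig | None = None) -> PredictionEvaluation:
    """Train on one population, evaluate r and beta on another."""
    solver = solver or SolverConfig()
    overlap = set(y_train.index) & set(y_test.index)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:3]}")
    ids = list(y_train.index) + list(y_test.index)
    sub = G.submatrix(ids)
    fit = fit_gblup(y_train, sub, solver)
    gebv = fit.gebv.loc[list(y_test.index)].to_numpy()
    return _evaluate(list(y_test.index), gebv[None, :], y_test.to_numpy(float),
                     {"experiment": "cross_population",
                      "n_train": y_train.size, "n_test": y_test.size})


def combined_cv(populations: dict[str, pd.Series],
                G: GenomicRelationshipMatrix,
                scheme: CVScheme | None = None,
                solver: SolverConfig | None = None) -> dict[str, PredictionEvaluation]:
    """Pooled k-fold CV over several populations, reported per population.

    All individuals enter one training pool; folds cut across populations.
    Returns one evaluation per population label plus "combined" for the
    pooled set.  Results are invariant to the order of the labels.
    """
    scheme = scheme or CVScheme()
    solver = solver or SolverConfig()
    labels = list(populations)
    all_ids = [s for lab in labels for s in populations[lab].index]
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("populations share sample ids")
    y = pd.concat([populations[lab] for lab in labels])
    y = y.loc[sorted(all_ids)]          # label-order invariance
    ids = list(y.index)
    Gm = _check_psd(G.submatrix(ids).matrix)
    yv = y.to_numpy(float)
    gebvs = _kfold_gebv_matrix(yv, Gm, scheme, solver)

    out = {"combined": _evaluate(ids, gebvs, yv,
                                 {"experiment": "combined_cv", "n": len(ids)})}
    pos = {s: i for i, s in enumerate(ids)}
    for lab in labels:
        idx = np.array([pos[s] for s in populations[lab].index])
        out[lab] = _evaluate([ids[i] for i in idx], gebvs[:, idx], yv[idx],
                             {"experiment": "combined_cv", "population": lab,
                              "n": idx.size})
    return out


def _grid_seed(master: int, counter: int) -> int:
    return int(np.random.SeedSequence((master, counter)).generate_state(1)[0] % (2**31))


def run_experiment_grid(
    af: AlleleFrequencyMatrix,
    phenotypes: pd.Series,
    populations: dict[str, list[str]],
    marker_sets=("full",),
    n_random_markers: int = 7_800,
    n_random_sets: int = 10,
    subsample_sizes=(),
    n_subsamples: int = 10,
    scheme: CVScheme | None = None,
    solver: SolverConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the {training} x {prediction} x {marker set} x {subsample} grid.

    ``marker_sets`` may contain "full", "stringent" and "random";
    ``subsample_sizes`` restricts every population to random subsets of the
    given sizes (repeated ``n_subsamples`` times), emulating small-panel
    designs.  Returns a tidy table with mean and s.d. of r and beta over
    the marker-set/subsample instances; infeasible cells are recorded with
    status "failed" and the grid continues.  Every cell derives its own
    seed from ``seed`` and a running counter, so any cell can be re-run in
    isolation.
    """
    scheme = scheme or CVScheme()
    solver = solver or SolverConfig()
    instances: list[tuple[str, AlleleFrequencyMatrix]] = []
    for ms in marker_sets:
        if ms == "full":
            instances.append(("full", af))
        elif ms == "stringent":
            instances.append(("stringent", stringent_marker_set(af)[0]))
        elif ms == "random":
            for j, sub in enumerate(random_marker_sets(
                    af, n_random_markers, n_random_sets, seed=_grid_seed(seed, 10_000))):
                instances.append((f"random", sub))
        else:
            raise ValueError(f"unknown marker set {ms!r}")

    sub_specs: list[tuple[int | None, int]] = [(None, 0)]
    for size in subsample_sizes:
        sub_specs += [(size, j) for j in range(n_subsamples)]

    counter = 0
    results: dict[tuple, list[dict]] = {}
    for set_name, af_i in instances:
        available = set(af_i.sample_ids)
        G = grm_from_af(af_i)
        for size, draw in sub_specs:
            counter += 1
            rng = np.random.default_rng(_grid_seed(seed, counter))
            pops = {}
            for lab, pids in populations.items():
                ids = [s for s in pids if s in available and s in phenotypes.index]
                if size is not None and len(ids) > size:
                    ids = list(rng.choice(ids, size=size, replace=False))
                pops[lab] = phenotypes.loc[ids]
            labels = list(pops)

            def record(train, pred, r, beta, n_train, n_pred, status="ok"):
                key = (train, pred, set_name, size)
                results.setdefault(key, []).append(
                    {"r": r, "beta": beta, "n_train": n_train,
                     "n_pred": n_pred, "status": status})

            cell_scheme = CVScheme(k=scheme.k, n_repeats=scheme.n_repeats,
                                   seed=_grid_seed(seed, counter), mode=scheme.mode)
            for train in labels:
                for pred in labels:
                    try:
                        if train == pred:
                            ev = kfold_cv(pops[pred], G, cell_scheme, solver)
                            record(train, pred, ev.r, ev.beta,
                                   pops[train].size, pops[pred].size)
                        else:
                            ev = cross_population(pops[train], pops[pred], G, solver)
                            record(train, pred, ev.r, ev.beta,
                                   pops[train].size, pops[pred].size)
                    except (ValueError, np.linalg.LinAlgError) as exc:
                        record(train, pred, np.nan, np.nan,
                               pops[train].size, pops[pred].size, f"failed: {exc}")
            try:
                evs = combined_cv(pops, G, cell_scheme, solver)
                for pred in labels:
                    record("combined", pred, evs[pred].r, evs[pred].beta,
                           sum(p.size for p in pops.values()), pops[pred].size)
            except (ValueError, np.linalg.LinAlgError) as exc:
                for pred in labels:
                    record("combined", pred, np.nan, np.nan,
                           sum(p.size for p in pops.values()), pops[pred].size,
                           f"failed: {exc}")

    rows = []
    for (train, pred, set_name, size), cells in results.items():
        ok = [c for c in cells if c["status"] == "ok"]
        rs = np.array([c["r"] for c in ok])
        bs = np.array([c["beta"] for c in ok])
        rows.append({
            "training_set": train, "prediction_set": pred,
            "marker_set": set_name,
            "subsample_size": size if size is not None else 0,
            "n_runs": len(ok),
            "r_mean": rs.mean() if ok else np.nan,
            "r_sd": rs.std(ddof=1) if len(ok) > 1 else 0.0 if ok else np.nan,
            "beta_mean": bs.mean() if ok else np.nan,
            "beta_sd": bs.std(ddof=1) if len(ok) > 1 else 0.0 if ok else np.nan,
            "n_train": ok[0]["n_train"] if ok else cells[0]["n_train"],
            "n_pred": ok[0]["n_pred"] if ok else cells[0]["n_pred"],
            "status": "ok" if ok else cells[0]["status"],
        })
    return pd.DataFrame(rows)


def load_config(path) -> dict:
    """Read a YAML pipeline configuration file."""
    import yaml
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def plot_observed_vs_predicted(ev: PredictionEvaluation, path) -> None:
    """Diagnostic scatter of observed phenotype against mean GEBV."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(ev.gebv, ev.y, s=8, alpha=0.6)
    ax.set_xlabel("GEBV")
    ax.set_ylabel("observed phenotype")
    ax.set_title(f"r = {ev.r:.2f}, beta = {ev.beta:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
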