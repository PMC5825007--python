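"""Multi-response MARS species distribution models with inventory pseudo-absences.

The survey data are presence-only: a site enters the data because *some*
species was recorded there.  Sites where other species were recorded but a
focal species was not are treated as that species' pseudo-absences
("inventory pseudo-absences"), giving a dense site-by-species 0/1 response
matrix that all species in a batch share.

The model is multivariate adaptive regression splines (MARS) fitted jointly
to all response columns: a single shared expansion of mirrored hinge basis
functions h(x; k, s) = max(0, s*(x - k)), products of up to ``max_degree``
hinges, grown greedily to minimize the residual sum of squares summed over
all species, then pruned by a multi-response generalized cross-validation
(GCV) criterion.  Each species keeps its own coefficient vector over the
shared basis.  Predictions are least-squares responses clamped to [0, 1].

Because concurrent fitting of very large batches is numerically fragile, the
species pool is partitioned into random groups before fitting (default
trigger: more than 300 species per batch).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .grids import EnvStack
from .synthgeo import OccurrenceTable

logger = logging.getLogger(__name__)

DEFAULT_PREDICTORS = (
    "elevation",
    "slope",
    "northness",
    "annual_mean_temp",
    "temp_seasonality",
    "temp_warmest_q",
    "temp_coldest_q",
    "annual_precip",
    "precip_wettest_q",
    "precip_driest_q",
)


# ---------------------------------------------------------------------------
# data containers


@dataclass
class SiteSpeciesMatrix:
    """Distinct survey sites x species responses, with extracted predictors."""

    sites: np.ndarray          # (n, 2) int (row, col), lexicographically sorted
    predictor_names: tuple[str, ...]
    X: np.ndarray              # (n, p) predictor values
    Y: np.ndarray              # (n, S) 0/1 responses
    species_ids: list[str]

    @property
    def n_sites(self) -> int:
        return self.sites.shape[0]

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def subset(self, species: list[str]) -> "SiteSpeciesMatrix":
        idx = [self.species_ids.index(s) for s in species]
        return SiteSpeciesMatrix(
            sites=self.sites,
            predictor_names=self.predictor_names,
            X=self.X,
            Y=self.Y[:, idx],
            species_ids=list(species),
        )


def build_site_species_matrix(
    occurrences: OccurrenceTable,
    env: EnvStack,
    predictors: tuple[str, ...] = DEFAULT_PREDICTORS,
) -> SiteSpeciesMatrix:
    """Assemble the site-by-species matrix from point records.

    One row per distinct (row, col) site; response(site, s) = 1 iff species s
    was recorded there, else 0 (an inventory pseudo-absence).  Species with
    zero records are excluded with a warning.
    """
    n_rows, n_cols = env.shape
    if np.any(occurrences.rows < 0) or np.any(occurrences.rows >= n_rows):
        raise ValueError("occurrence rows fall off the grid")
    if np.any(occurrences.cols < 0) or np.any(occurrences.cols >= n_cols):
        raise ValueError("occurrence cols fall off the grid")

    sites = np.unique(np.stack([occurrences.rows, occurrences.cols], axis=1), axis=0)
    site_index = {(int(r), int(c)): i for i, (r, c) in enumerate(sites)}
    species_ids = sorted(set(occurrences.species_ids))
    sp_index = {s: j for j, s in enumerate(species_ids)}

    Y = np.zeros((sites.shape[0], len(species_ids)))
    for s, r, c in zip(occurrences.species_ids, occurrences.rows, occurrences.cols):
        Y[site_index[(int(r), int(c))], sp_index[s]] = 1.0

    empty = [s for j, s in enumerate(species_ids) if Y[:, j].sum() == 0]
    if empty:
        logger.warning("excluding %d species with zero records", len(empty))
        keep = [j for j, s in enumerate(species_ids) if s not in set(empty)]
        Y = Y[:, keep]
        species_ids = [species_ids[j] for j in keep]

    X = env.predictor_matrix(sites[:, 0], sites[:, 1], predictors)
    return SiteSpeciesMatrix(
        sites=sites, predictor_names=tuple(predictors), X=X, Y=Y,
        species_ids=species_ids,
    )


def partition_species_groups(
    species_ids: list[str], n_groups: int, seed: int = 0
) -> list[list[str]]:
    """Randomly partition species into fitting groups.

    All groups have size floor(S / n_groups) except the last, which absorbs
    the remainder (e.g. 2,297 species in 15 groups -> fourteen groups of 153
    and one of 155).
    """
    S = len(species_ids)
    if n_groups < 1 or n_groups > S:
        raise ValueError(f"n_groups must be in [1, {S}]")
    rng = np.random.default_rng(seed)
    ids = list(species_ids)
    perm = rng.permutation(S)
    shuffled = [ids[i] for i in perm]
    base = S // n_groups
    groups = [shuffled[i * base : (i + 1) * base] for i in range(n_groups - 1)]
    groups.append(shuffled[(n_groups - 1) * base :])
    return groups


def n_groups_for(n_species: int, max_batch: int = 300) -> int:
    """Number of fitting groups needed so no batch exceeds ``max_batch``."""
    return max(1, -(-n_species // max_batch))


# ---------------------------------------------------------------------------
# MARS model


Hinge = tuple[int, float, int]  # (predictor index, knot, sign)


@dataclass(frozen=True)
class BasisFunction:
    """Product of hinge factors; the empty product is the intercept."""

    factors: tuple[Hinge, ...] = ()

    @property
    def degree(self) -> int:
        return len(self.factors)

    def evaluate(self, X: np.ndarray) -> np.ndarray:
        out = np.ones(X.shape[0])
        for v, k, s in self.factors:
            out *= np.maximum(0.0, s * (X[:, v] - k))
        return out

    def variables(self) -> set[int]:
        return {v for v, _, _ in self.factors}


@dataclass
class MarsConfig:
    max_basis: int = 21       # total basis functions, intercept included
    max_degree: int = 2
    gcv_penalty: float = 3.0
    max_knots: int = 50       # candidate knots per (parent, variable)
    min_rss_decrease: float = 1e-12  # relative to initial total RSS


@dataclass
class MarsModel:
    """Shared hinge basis with per-species coefficient vectors."""

    basis: list[BasisFunction]        # basis[0] is always the intercept
    coef: np.ndarray                  # (len(basis), S)
    gcv: float
    predictor_names: tuple[str, ...]
    species_ids: list[str]
    forward_rss: list[float] = field(default_factory=list)

    @property
    def selected_predictors(self) -> set[str]:
        out: set[int] = set()
        for bf in self.basis:
            out |= bf.variables()
        return {self.predictor_names[v] for v in out}

    def design_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.column_stack([bf.evaluate(X) for bf in self.basis])

    def predict(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """(n, S) predicted occurrence probabilities, clamped to [0, 1]."""
        raw = self.design_matrix(X) @ self.coef
        return np.clip(raw, 0.0, 1.0) if clamp else raw

    def to_json_dict(self) -> dict:
        return {
            "predictor_names": list(self.predictor_names),
            "species_ids": list(self.species_ids),
            "gcv": self.gcv,
            "basis": [
                [[int(v), float(k), int(s)] for v, k, s in bf.factors]
                for bf in self.basis
            ],
            "coef": self.coef.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "MarsModel":
        basis = [
            BasisFunction(tuple((int(v), float(k), int(s)) for v, k, s in fs))
            for fs in d["basis"]
        ]
        return cls(
            basis=basis,
            coef=np.asarray(d["coef"], dtype=float),
            gcv=float(d["gcv"]),
            predictor_names=tuple(d["predictor_names"]),
            species_ids=list(d["species_ids"]),
        )


def _candidate_knots(values: np.ndarray, max_knots: int) -> np.ndarray:
    uniq = np.unique(values)
    if uniq.size <= max_knots:
        return uniq
    qs = np.linspace(0, 1, max_knots)
    return np.unique(np.quantile(uniq, qs, method="nearest"))


def _gcv_cost(M: int, penalty: float) -> float:
    return M + penalty * (M - 1) / 2.0


def _multi_gcv(rss_total: float, n: int, S: int, M: int, penalty: float) -> float:
    c = _gcv_cost(M, penalty)
    if c >= n:
        return np.inf
    return (rss_total / (n * S)) / (1.0 - c / n) ** 2


def fit_mars_multiresponse(
    matrix: SiteSpeciesMatrix, config: MarsConfig | None = None
) -> MarsModel:
    """Fit a multi-response MARS model to a site-by-species matrix.

    Forward pass: starting from the intercept, repeatedly add the mirrored
    hinge pair (parent basis x variable x knot, both signs) that most reduces
    the residual sum of squares summed over all response columns, until
    ``max_basis`` functions exist or no candidate helps.  Candidate knots are
    the observed predictor values where the parent is active, thinned to at
    most ``max_knots`` quantiles.  Backward pass: delete basis functions one
    at a time, each time the deletion that minimizes the multi-response GCV
        GCV = (RSS_total / (n S)) / (1 - C(M)/n)^2,  C(M) = M + penalty (M-1)/2,
    stopping when no deletion lowers the GCV.
    """
    config = config or MarsConfig()
    X, Y = matrix.X, matrix.Y
    n, S = Y.shape
    if n < 2:
        raise ValueError("need at least 2 sites to fit")
    if not np.all(np.isfinite(X)):
        raise ValueError("predictors must be finite")

    basis: list[BasisFunction] = [BasisFunction(())]
    B = np.ones((n, 1))
    rss0 = float(((Y - Y.mean(axis=0)) ** 2).sum()) + 1e-300
    forward_rss: list[float] = []

    while B.shape[1] + 1 < config.max_basis + 1 and B.shape[1] < n:
        Q, _ = np.linalg.qr(B)
        Yres = Y - Q @ (Q.T @ Y)
        best = None  # (reduction, parent_idx, var, knot)
        for j, parent in enumerate(basis):
            if parent.degree >= config.max_degree:
                continue
            bj = B[:, j]
            active = bj > 0
            if active.sum() < 2:
                continue
            for v in range(X.shape[1]):
                if v in parent.variables():
                    continue
                knots = _candidate_knots(X[active, v], config.max_knots)
                if knots.size == 0:
                    continue
                red, kbest = _best_knot_reduction(bj, X[:, v], knots, Q, Yres)
                if red is not None and (best is None or red > best[0] + 1e-15):
                    best = (red, j, v, kbest)
        if best is None or best[0] <= config.min_rss_decrease * rss0:
            break
        _, j, v, k = best
        parent = basis[j]
        added = 0
        for sign in (+1, -1):
            col = parent.evaluate(X) * np.maximum(0.0, sign * (X[:, v] - k))
            Qcur, _ = np.linalg.qr(B)
            resid = col - Qcur @ (Qcur.T @ col)
            if float(resid @ resid) <= 1e-10 * max(1.0, float(col @ col)):
                logger.debug("dropping numerically dependent hinge (v=%d, k=%g, s=%d)", v, k, sign)
                continue
            basis.append(BasisFunction(parent.factors + ((v, float(k), sign),)))
            B = np.column_stack([B, col])
            added += 1
            if B.shape[1] >= config.max_basis:
                break
        if added == 0:
            break
        coef, _, _, _ = np.linalg.lstsq(B, Y, rcond=None)
        forward_rss.append(float(((Y - B @ coef) ** 2).sum()))

    # backward pruning by multi-response GCV
    def rss_for(cols: list[int]) -> float:
        Bsub = B[:, cols]
        coef, _, _, _ = np.linalg.lstsq(Bsub, Y, rcond=None)
        return float(((Y - Bsub @ coef) ** 2).sum())

    cols = list(range(B.shape[1]))
    cur_gcv = _multi_gcv(rss_for(cols), n, S, len(cols), config.gcv_penalty)
    while len(cols) > 1:
        cand = []
        for drop in cols[1:]:  # intercept is never deleted
            sub = [c for c in cols if c != drop]
            cand.append((_multi_gcv(rss_for(sub), n, S, len(sub), config.gcv_penalty), drop))
        gbest, drop = min(cand, key=lambda t: (t[0], t[1]))
        if gbest <= cur_gcv:
            cols = [c for c in cols if c != drop]
            cur_gcv = gbest
        else:
            break

    basis = [basis[c] for c in cols]
    Bfinal = B[:, cols]
    coef, _, _, _ = np.linalg.lstsq(Bfinal, Y, rcond=None)
    return MarsModel(
        basis=basis,
        coef=coef,
        gcv=cur_gcv,
        predictor_names=matrix.predictor_names,
        species_ids=list(matrix.species_ids),
        forward_rss=forward_rss,
    )


def _best_knot_reduction(bj, xv, knots, Q, Yres):
    """Joint RSS reduction of the mirrored hinge pair, maximized over knots.

    Both signed hinges are residualized against the current basis (through
    its orthonormal factor Q); per knot the exact two-column least-squares
    reduction is obtained from the 2x2 Gram system.  Near-singular pairs fall
    back to the better single column.
    """
    diff = xv[:, None] - knots[None, :]
    Hp = np.maximum(0.0, diff) * bj[:, None]
    Hm = np.maximum(0.0, -diff) * bj[:, None]
    Hp = Hp - Q @ (Q.T @ Hp)
    Hm = Hm - Q @ (Q.T @ Hm)
    gpp = np.einsum("ij,ij->j", Hp, Hp)
    gmm = np.einsum("ij,ij->j", Hm, Hm)
    gpm = np.einsum("ij,ij->j", Hp, Hm)
    Ap = Hp.T @ Yres  # (K, S)
    Am = Hm.T @ Yres
    det = gpp * gmm - gpm**2
    scale = np.maximum(gpp * gmm, 1e-300)
    ok = det > 1e-10 * scale
    red = np.zeros(knots.size)
    if ok.any():
        num = (
            gmm[ok, None] * Ap[ok] ** 2
            - 2.0 * gpm[ok, None] * Ap[ok] * Am[ok]
            + gpp[ok, None] * Am[ok] ** 2
        )
        red[ok] = num.sum(axis=1) / det[ok]
    single_p = np.where(gpp > 1e-12, (Ap**2).sum(axis=1) / np.maximum(gpp, 1e-300), 0.0)
    single_m = np.where(gmm > 1e-12, (Am**2).sum(axis=1) / np.maximum(gmm, 1e-300), 0.0)
    red[~ok] = np.maximum(single_p, single_m)[~ok]
    if red.size == 0 or red.max() <= 0:
        return None, None
    kidx = int(np.argmax(red))
    return float(red[kidx]), float(knots[kidx])


# ---------------------------------------------------------------------------
# prediction and evaluation


def predict_probabilities(model: MarsModel, env: EnvStack) -> dict[str, np.ndarray]:
    """Per-species occurrence-probability rasters, clamped to [0, 1]."""
    missing = [p for p in model.selected_predictors if p not in env.layers]
    if missing:
        raise KeyError(f"environment is missing predictor layer(s): {missing}")
    for p in model.predictor_names:
        if p not in env.layers:
            raise KeyError(f"environment is missing predictor layer(s): ['{p}']")
    n_rows, n_cols = env.shape
    Xfull = np.column_stack(
        [env[p].ravel() for p in model.predictor_names]
    )
    probs = model.predict(Xfull)  # (cells, S)
    return {
        s: probs[:, j].reshape(n_rows, n_cols)
        for j, s in enumerate(model.species_ids)
    }


def compute_auc(presence_scores, absence_scores) -> float:
    """AUC by the Mann-Whitney formulation with midrank tie handling.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n1 * n0).  Returns NaN if
    either side is empty (AUC undefined).
    """
    p = np.asarray(presence_scores, dtype=float)
    a = np.asarray(absence_scores, dtype=float)
    if p.size == 0 or a.size == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([p, a]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * a.size))


@dataclass
class ModelEval:
    """Per-species fit AUC for one fitted group."""

    species_ids: list[str]
    n_records: np.ndarray
    auc: np.ndarray

    @property
    def mean_auc(self) -> float:
        return float(np.nanmean(self.auc))

    @property
    def sd_auc(self) -> float:
        return float(np.nanstd(self.auc, ddof=1))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"species_id": self.species_ids, "n_records": self.n_records, "auc": self.auc}
        )


def evaluate_model(model: MarsModel, matrix: SiteSpeciesMatrix) -> ModelEval:
    """Fit-data AUC per species: presences vs all inventory pseudo-absences."""
    scores = model.predict(matrix.X)
    aucs = np.empty(matrix.n_species)
    n_rec = np.empty(matrix.n_species, dtype=int)
    for j in range(matrix.n_species):
        pres = matrix.Y[:, j] == 1
        aucs[j] = compute_auc(scores[pres, j], scores[~pres, j])
        n_rec[j] = int(matrix.Y[:, j].sum())
    return ModelEval(species_ids=list(matrix.species_ids), n_records=n_rec, auc=aucs)


def fit_grouped(
    matrix: SiteSpeciesMatrix,
    seed: int = 0,
    max_batch: int = 300,
    n_groups: int | None = None,
    config: MarsConfig | None = None,
) -> list[tuple[MarsModel, SiteSpeciesMatrix]]:
    """Partition species into batches and fit one multi-response model each."""
    if n_groups is None:
        n_groups = n_groups_for(matrix.n_species, max_batch)
    groups = partition_species_groups(matrix.species_ids, n_groups, seed=seed)
    out = []
    for g in groups:
        sub = matrix.subset(g)
        out.append((fit_mars_multiresponse(sub, config), sub))
    return out
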