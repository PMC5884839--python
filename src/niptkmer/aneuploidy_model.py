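"""Coverage regression, z-score trisomy calling, fetal sex, and Mahalanobis QC.

Model
-----
Per-chromosome coverage is C_sc = K_sc / L_c. For each target chromosome an
ordinary least-squares model *without intercept* predicts its coverage from
the coverages of the other autosomes plus the sample GC fraction:

    C'_sc = beta_1 C_1 + ... + beta_p C_p + beta_GC * GC_S,
    beta = (X^T X)^{-1} X^T y  fitted on declared euploid reference samples.

The relative residual D_sc = (C_sc - C'_sc) / C'_sc is standardized against
the reference population (sample SD, n-1 denominator):

    Z_sc = (D_sc - mean(D_ref)) / SD(D_ref),

and a chromosome is called *elevated* (trisomy risk) when Z_sc exceeds a
one-sided cut-off (default 3.5 SD, giving an analytic false-positive rate of
~0.023% under normality). Fetal sex is decided by four sex-chromosome models
(X and Y, each fitted on female- and male-fetus reference pregnancies) and
the hypothesis minimizing the joint squared z of X and Y. The Mahalanobis
distance of the sample's normalized coverage profile from the reference
centroid serves as a quality-control metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sample_counter import GC_COLUMN, DataMatrix
from .list_builder import sort_chromosomes

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3.5
# Relative floor on the residual SD used in sex scoring: guards the degenerate
# chrY-in-female-references model whose residuals are identically ~0.
SEX_SD_FLOOR = 1e-3


def chromosome_kind(name: str) -> str:
    base = name.removeprefix("chr")
    if base.isdigit():
        return "autosome"
    if base in ("X", "Y"):
        return base
    return "other"


def autosomes_of(columns: Iterable[str]) -> list[str]:
    return [c for c in sort_chromosomes([c for c in columns if chromosome_kind(c) == "autosome"])]


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def coverage(k_sc: float, l_c: float) -> float:
    """C_sc = K_sc / L_c."""
    if l_c <= 0:
        raise ValueError("k-mer list size L_c must be positive")
    return k_sc / l_c


def coverage_frame(matrix: DataMatrix) -> pd.DataFrame:
    """Data matrix -> per-chromosome coverages C_sc (gc column passed through)."""
    frame = matrix.frame.copy()
    for chrom in matrix.chromosomes:
        frame[chrom] = frame[chrom] / matrix.l_c[chrom]
    return frame


@dataclass
class CoverageVector:
    """One sample's per-chromosome coverages plus GC fraction."""

    c_sc: dict[str, float]
    gc_s: float

    def value(self, key: str) -> float:
        if key == GC_COLUMN:
            return self.gc_s
        if key not in self.c_sc:
            raise KeyError(f"missing predictor {key!r}")
        return self.c_sc[key]

    @classmethod
    def from_row(cls, row: pd.Series) -> "CoverageVector":
        c = {k: float(v) for k, v in row.items() if k != GC_COLUMN}
        return cls(c, float(row[GC_COLUMN]))


@dataclass
class RegressionModel:
    """OLS coefficients for one target chromosome plus reference statistics."""

    target: str
    predictors: tuple[str, ...]
    beta: np.ndarray
    d_ref_mean: float | None
    d_ref_sd: float | None
    resid_ref_sd: float
    reference_level: float  # mean reference coverage over non-GC predictors
    reference_ids: tuple[str, ...]

    def to_jsonable(self) -> dict:
        return {
            "target": self.target,
            "predictors": list(self.predictors),
            "beta": [float(b) for b in self.beta],
            "d_ref_mean": self.d_ref_mean,
            "d_ref_sd": self.d_ref_sd,
            "resid_ref_sd": self.resid_ref_sd,
            "reference_level": self.reference_level,
            "reference_ids": list(self.reference_ids),
        }

    @classmethod
    def from_jsonable(cls, d: dict) -> "RegressionModel":
        return cls(
            target=d["target"],
            predictors=tuple(d["predictors"]),
            beta=np.asarray(d["beta"], dtype=float),
            d_ref_mean=d["d_ref_mean"],
            d_ref_sd=d["d_ref_sd"],
            resid_ref_sd=d["resid_ref_sd"],
            reference_level=d["reference_level"],
            reference_ids=tuple(d["reference_ids"]),
        )


def default_predictors(target: str, columns: Iterable[str]) -> tuple[str, ...]:
    """Autosome target: the other autosomes + GC; X/Y target: all autosomes + GC.

    Sex chromosomes are never predictors, keeping autosome models independent
    of fetal sex.
    """
    autos = autosomes_of(columns)
    kind = chromosome_kind(target)
    if kind == "autosome":
        preds = [c for c in autos if c != target]
    elif kind in ("X", "Y"):
        preds = autos
    else:
        raise ValueError(f"cannot build default predictors for {target!r}")
    return tuple(preds) + (GC_COLUMN,)


def fit_model(
    coverages: pd.DataFrame,
    reference_ids: Sequence[str],
    target: str,
    predictors: Sequence[str] | None = None,
    min_extra: int = 5,
    intercept: bool = False,
    max_condition: float = 1e10,
) -> RegressionModel:
    """Fit the no-intercept OLS coverage model for one target chromosome.

    ``coverages`` holds C_sc values (and GC) with samples as rows. Only the
    declared euploid ``reference_ids`` enter the fit. Requires at least
    ``len(predictors) + min_extra`` reference samples and a well-conditioned
    design; otherwise raises advising more reference samples.
    """
    if predictors is None:
        predictors = default_predictors(target, coverages.columns)
    predictors = tuple(predictors)
    if target in predictors:
        raise ValueError(f"target {target!r} cannot be its own predictor")
    missing = [s for s in reference_ids if s not in coverages.index]
    if missing:
        raise KeyError(f"reference samples absent from matrix: {missing}")
    X = coverages.loc[list(reference_ids), list(predictors)].to_numpy(dtype=float)
    y = coverages.loc[list(reference_ids), target].to_numpy(dtype=float)
    if intercept:
        X = np.column_stack([X, np.ones(len(X))])
    n, p = X.shape
    if n < p + min_extra:
        raise ValueError(
            f"only {n} reference samples for {p} predictors; "
            f"need at least {p + min_extra} — add more reference samples"
        )
    cond = np.linalg.cond(X)
    if not np.isfinite(cond) or cond > max_condition:
        raise ValueError(
            f"design matrix for target {target} is ill-conditioned (cond={cond:.3g}); "
            "add more reference samples or drop collinear predictors"
        )
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    if intercept:
        predictors = predictors + ("__intercept__",)
    pred = X @ beta
    resid = y - pred
    resid_sd = float(resid.std(ddof=1))
    if (pred > 0).all():
        d = resid / pred
        d_mean, d_sd = float(d.mean()), float(d.std(ddof=1))
        if d_sd == 0.0:
            log.warning("target %s: reference D_sc has zero SD (noiseless fit?)", target)
    else:
        d_mean = d_sd = None
    non_gc = [c for c in predictors if c not in (GC_COLUMN, "__intercept__")]
    level = float(coverages.loc[list(reference_ids), non_gc].to_numpy().mean()) if non_gc else 1.0
    return RegressionModel(
        target=target,
        predictors=predictors,
        beta=np.asarray(beta, dtype=float),
        d_ref_mean=d_mean,
        d_ref_sd=d_sd,
        resid_ref_sd=resid_sd,
        reference_level=level,
        reference_ids=tuple(reference_ids),
    )


def predict(model: RegressionModel, sample: CoverageVector | Mapping[str, float] | pd.Series) -> float:
    """C'_sc: dot product of beta with the sample's predictor values (no intercept)."""
    values = []
    for key in model.predictors:
        if key == "__intercept__":
            values.append(1.0)
            continue
        if isinstance(sample, CoverageVector):
            values.append(sample.value(key))
        else:
            if key not in sample:
                raise KeyError(f"sample missing predictor {key!r}")
            values.append(float(sample[key]))
    return float(np.dot(model.beta, values))


def normalized_diff(c_sc: float, c_pred: float) -> float:
    """D_sc = (C_sc - C'_sc) / C'_sc; the *predicted* coverage is the denominator."""
    if not np.isfinite(c_pred) or c_pred <= 0:
        raise ValueError(f"predicted coverage must be positive, got {c_pred}")
    return (c_sc - c_pred) / c_pred


def zscore(d_sc: float, model: RegressionModel) -> float:
    """Z_sc = (D_sc - mean(D_ref)) / SD(D_ref)."""
    # an SD at float-noise level means a degenerate (noiseless) reference fit
    if model.d_ref_sd is None or model.d_ref_sd < 1e-15:
        raise ValueError(
            f"model for {model.target} has degenerate reference SD; cannot z-score"
        )
    return (d_sc - model.d_ref_mean) / model.d_ref_sd


def call_aneuploidy(z_sc: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """'elevated' iff Z_sc > cutoff (strict, one-sided: gains only)."""
    if not np.isfinite(z_sc):
        raise ValueError(f"non-finite z-score {z_sc}")
    return "elevated" if z_sc > cutoff else "normal"


def false_positive_rate_percent(cutoff: float = DEFAULT_CUTOFF) -> float:
    """One-sided standard-normal tail beyond the cut-off, as a percentage."""
    return float(norm.sf(cutoff) * 100.0)


def expected_shift(n: float) -> float:
    """Relative coverage change of a trisomic chromosome at fetal fraction n%.

    (100 + 3/2 n) / (100 + n) - 1, algebraically 0.5 n / (100 + n). The
    parametrization holds the maternal contribution at 100; the weight-based
    simulator convention (fetal reads = n% of the total) gives ~0.5 n/100
    instead — see docs/methods.md.
    """
    if not 0.0 <= n <= 100.0:
        raise ValueError(f"fetal fraction percent must be in [0, 100], got {n}")
    return (100.0 + 1.5 * n) / (100.0 + n) - 1.0


def mahalanobis(
    sample_vector: np.ndarray,
    control_mean: np.ndarray,
    control_covariance: np.ndarray,
    max_condition: float = 1e12,
) -> float:
    """D_M = sqrt((x - mu)^T S^{-1} (x - mu)).

    A near-singular covariance is ridge-regularized by 1e-8 * trace/dim
    (logged); otherwise the quadratic form is solved exactly.
    """
    x = np.asarray(sample_vector, dtype=float)
    mu = np.asarray(control_mean, dtype=float)
    S = np.asarray(control_covariance, dtype=float)
    if x.shape != mu.shape or S.shape != (x.size, x.size):
        raise ValueError(
            f"dimension mismatch: x {x.shape}, mean {mu.shape}, cov {S.shape}"
        )
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > max_condition:
        ridge = 1e-8 * np.trace(S) / S.shape[0]
        log.warning("covariance ill-conditioned (cond=%.3g); adding ridge %.3g", cond, ridge)
        S = S + ridge * np.eye(S.shape[0])
    diff = x - mu
    return float(np.sqrt(diff @ np.linalg.solve(S, diff)))


# ---------------------------------------------------------------------------
# Fetal sex
# ---------------------------------------------------------------------------

SEXES = ("female", "male")


def sex_residual_z(model: RegressionModel, sample: CoverageVector) -> float:
    """Absolute-residual z for sex scoring: (C_obs - C') / SD_ref(resid).

    Uses the residual (not relative-difference) scale because the
    female-hypothesis chrY model predicts coverage ~0, where D_sc is
    undefined. The SD is floored at SEX_SD_FLOOR times the mean reference
    autosome coverage so an identically-zero reference residual (chrY in
    female pregnancies) cannot blow up on numerical dust.
    """
    c_obs = sample.value(model.target)
    c_pred = predict(model, sample)
    sd = max(model.resid_ref_sd, SEX_SD_FLOOR * model.reference_level)
    return (c_obs - c_pred) / sd


@dataclass
class SexCall:
    sex: str  # "female" | "male" | "ambiguous"
    scores: dict  # per hypothesis: {"z_x":, "z_y":, "score":}


def determine_sex(
    sample: CoverageVector,
    sex_models: Mapping[tuple[str, str], RegressionModel],
    rel_tol: float = 1e-9,
) -> SexCall:
    """Pick the fetal-sex hypothesis minimizing z_X^2 + z_Y^2.

    ``sex_models`` maps ("X"|"Y", "female"|"male") to the model fitted on
    reference pregnancies of that fetal sex. An exact tie is reported as
    'ambiguous' rather than silently resolved.
    """
    for key in (("X", "female"), ("Y", "female"), ("X", "male"), ("Y", "male")):
        if key not in sex_models:
            raise ValueError(f"missing sex model {key}")
    scores = {}
    for hyp in SEXES:
        zx = sex_residual_z(sex_models[("X", hyp)], sample)
        zy = sex_residual_z(sex_models[("Y", hyp)], sample)
        scores[hyp] = {"z_x": zx, "z_y": zy, "score": zx * zx + zy * zy}
    sf, sm = scores["female"]["score"], scores["male"]["score"]
    denom = max(sf, sm, 1e-300)
    if abs(sf - sm) <= rel_tol * denom:
        sex = "ambiguous"
    else:
        sex = "female" if sf < sm else "male"
    return SexCall(sex=sex, scores=scores)


# ---------------------------------------------------------------------------
# Cohort-level caller
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeCall:
    chromosome: str
    c_obs: float
    c_pred: float
    d: float
    z: float
    call: str


@dataclass
class CallResult:
    sample_id: str
    chromosomes: dict[str, ChromosomeCall]
    sex: str | None
    sex_scores: dict | None
    d_m: float
    cutoff_used: float


class AneuploidyCaller:
    """Fitted cohort model: per-autosome OLS, four sex models, QC statistics.

    Models are fitted only on the declared euploid reference samples; a test
    sample never enters its own reference.
    """

    def __init__(
        self,
        models: dict[str, RegressionModel],
        sex_models: dict[tuple[str, str], RegressionModel] | None,
        qc_models: dict[str, RegressionModel],
        qc_dims: list[str],
        qc_mean: np.ndarray,
        qc_cov: np.ndarray,
        reference_ids: tuple[str, ...],
        cutoff: float = DEFAULT_CUTOFF,
    ):
        self.models = models
        self.sex_models = sex_models
        self.qc_models = qc_models
        self.qc_dims = qc_dims
        self.qc_mean = qc_mean
        self.qc_cov = qc_cov
        self.reference_ids = reference_ids
        self.cutoff = cutoff

    # -- fitting ------------------------------------------------------------

    @classmethod
    def fit(
        cls,
        matrix: DataMatrix,
        reference_ids: Sequence[str],
        reference_sexes: Mapping[str, str] | None = None,
        cutoff: float = DEFAULT_CUTOFF,
        min_extra: int = 5,
    ) -> "AneuploidyCaller":
        cov = coverage_frame(matrix)
        missing = [s for s in reference_ids if s not in cov.index]
        if missing:
            raise KeyError(f"reference samples absent from matrix: {missing}")
        autos = autosomes_of(cov.columns)
        models = {
            a: fit_model(cov, reference_ids, a, min_extra=min_extra) for a in autos
        }

        sex_chroms = [c for c in matrix.chromosomes if chromosome_kind(c) in ("X", "Y")]
        sex_models = None
        if len(sex_chroms) == 2 and reference_sexes is not None:
            x_name = next(c for c in sex_chroms if chromosome_kind(c) == "X")
            y_name = next(c for c in sex_chroms if chromosome_kind(c) == "Y")
            by_sex = {s: [r for r in reference_ids if reference_sexes.get(r) == s] for s in SEXES}
            for s in SEXES:
                if not by_sex[s]:
                    raise ValueError(f"no reference pregnancies with fetal sex {s!r}")
            sex_models = {}
            for s in SEXES:
                sex_models[("X", s)] = fit_model(cov, by_sex[s], x_name, min_extra=min_extra)
                sex_models[("Y", s)] = fit_model(cov, by_sex[s], y_name, min_extra=min_extra)

        # QC (Mahalanobis) vector: normalized coverages D_sc of every
        # chromosome (sex chromosomes via models fitted on all references,
        # mixed sexes) plus raw GC.
        qc_models = dict(models)
        for c in sex_chroms:
            try:
                qc_models[c] = fit_model(cov, reference_ids, c, min_extra=min_extra)
            except ValueError as exc:
                log.warning("QC model for %s dropped: %s", c, exc)
        qc_dims = [c for c in sort_chromosomes(qc_models) if cls._qc_usable(qc_models[c], cov, reference_ids)]
        ref_vecs = []
        for r in reference_ids:
            sample = CoverageVector.from_row(cov.loc[r])
            ref_vecs.append(cls._qc_vector_static(sample, qc_models, qc_dims))
        ref_mat = np.asarray(ref_vecs, dtype=float)
        qc_mean = ref_mat.mean(axis=0)
        qc_cov = np.cov(ref_mat, rowvar=False, ddof=1)
        caller = cls(
            models=models,
            sex_models=sex_models,
            qc_models=qc_models,
            qc_dims=qc_dims,
            qc_mean=qc_mean,
            qc_cov=qc_cov,
            reference_ids=tuple(reference_ids),
            cutoff=cutoff,
        )
        caller._coverages = cov
        return caller

    @staticmethod
    def _qc_usable(model: RegressionModel, cov: pd.DataFrame, reference_ids) -> bool:
        return model.d_ref_sd is not None and model.d_ref_sd > 0

    @staticmethod
    def _qc_vector_static(sample: CoverageVector, qc_models, qc_dims) -> np.ndarray:
        vals = []
        for c in qc_dims:
            m = qc_models[c]
            vals.append(normalized_diff(sample.value(c), predict(m, sample)))
        vals.append(sample.gc_s)
        return np.asarray(vals, dtype=float)

    # -- calling ------------------------------------------------------------

    def attach_matrix(self, matrix: DataMatrix) -> None:
        """Point the caller at (possibly new) samples counted on the same lists."""
        self._coverages = coverage_frame(matrix)

    def call_sample(self, sample_id: str) -> CallResult:
        cov = self._coverages
        if sample_id not in cov.index:
            raise KeyError(f"sample {sample_id!r} not in matrix")
        sample = CoverageVector.from_row(cov.loc[sample_id])
        chrom_calls = {}
        for chrom, model in self.models.items():
            c_obs = sample.value(chrom)
            c_pred = predict(model, sample)
            d = normalized_diff(c_obs, c_pred)
            z = zscore(d, model)
            chrom_calls[chrom] = ChromosomeCall(
                chromosome=chrom,
                c_obs=c_obs,
                c_pred=c_pred,
                d=d,
                z=z,
                call=call_aneuploidy(z, self.cutoff),
            )
        sex = sex_scores = None
        if self.sex_models is not None:
            sc = determine_sex(sample, self.sex_models)
            sex, sex_scores = sc.sex, sc.scores
        try:
            vec = self._qc_vector_static(sample, self.qc_models, self.qc_dims)
            d_m = mahalanobis(vec, self.qc_mean, self.qc_cov)
        except ValueError:
            d_m = float("nan")
        return CallResult(
            sample_id=sample_id,
            chromosomes=chrom_calls,
            sex=sex,
            sex_scores=sex_scores,
            d_m=d_m,
            cutoff_used=self.cutoff,
        )

    def call_samples(self, sample_ids: Sequence[str] | None = None) -> list[CallResult]:
        if sample_ids is None:
            sample_ids = [s for s in self._coverages.index if s not in self.reference_ids]
        return [self.call_sample(s) for s in sample_ids]

    # -- tabular output -----------------------------------------------------

    @staticmethod
    def chromosome_frame(results: Sequence[CallResult]) -> pd.DataFrame:
        rows = []
        for r in results:
            for chrom, cc in r.chromosomes.items():
                rows.append(
                    {
                        "sample_id": r.sample_id,
                        "chromosome": chrom,
                        "C_sc": cc.c_obs,
                        "C_pred": cc.c_pred,
                        "D_sc": cc.d,
                        "Z_sc": cc.z,
                        "call": cc.call,
                    }
                )
        return pd.DataFrame(rows)

    @staticmethod
    def sample_frame(results: Sequence[CallResult]) -> pd.DataFrame:
        rows = []
        for r in results:
            row = {
                "sample_id": r.sample_id,
                "sex": r.sex,
                "D_M": r.d_m,
                "cutoff": r.cutoff_used,
            }
            if r.sex_scores:
                for hyp in SEXES:
                    row[f"z_x_{hyp}"] = r.sex_scores[hyp]["z_x"]
                    row[f"z_y_{hyp}"] = r.sex_scores[hyp]["z_y"]
            rows.append(row)
        return pd.DataFrame(rows)

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path) -> None:
        payload = {
            "cutoff": self.cutoff,
            "reference_ids": list(self.reference_ids),
            "models": {c: m.to_jsonable() for c, m in self.models.items()},
            "sex_models": (
                {f"{t}|{s}": m.to_jsonable() for (t, s), m in self.sex_models.items()}
                if self.sex_models
                else None
            ),
            "qc_models": {c: m.to_jsonable() for c, m in self.qc_models.items()},
            "qc_dims": self.qc_dims,
            "qc_mean": self.qc_mean.tolist(),
            "qc_cov": self.qc_cov.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "AneuploidyCaller":
        with open(path) as fh:
            d = json.load(fh)
        sex_models = None
        if d["sex_models"] is not None:
            sex_models = {}
            for key, m in d["sex_models"].items():
                t, s = key.split("|")
                sex_models[(t, s)] = RegressionModel.from_jsonable(m)
        return cls(
            models={c: RegressionModel.from_jsonable(m) for c, m in d["models"].items()},
            sex_models=sex_models,
            qc_models={c: RegressionModel.from_jsonable(m) for c, m in d["qc_models"].items()},
            qc_dims=list(d["qc_dims"]),
            qc_mean=np.asarray(d["qc_mean"], dtype=float),
            qc_cov=np.asarray(d["qc_cov"], dtype=float),
            reference_ids=tuple(d["reference_ids"]),
            cutoff=float(d["cutoff"]),
        )
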