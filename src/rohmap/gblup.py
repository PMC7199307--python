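"""GBLUP mixed model for validating ROH regions against SCR.

The model is y = Xb + Zu + e with u ~ N(0, G sigma_g2) and e ~ N(0, I
sigma_e2), where G is the VanRaden method-1 genomic relationship matrix
computed from observed allele frequencies.  With one record per animal, Z
selects rows of G, so the covariance of y is

    V = sigma_g2 * G[idx, idx] + sigma_e2 * I.

Fixed effects are estimated by generalized least squares; variance components
by restricted maximum likelihood.  Because V has the single-kernel form above,
REML reduces to a one-dimensional profile likelihood in the variance ratio
lambda = sigma_g2 / sigma_e2 after an eigendecomposition of the (sub-)GRM:
rotating y and X by the eigenvectors diagonalizes V, each likelihood
evaluation is O(n p^2), and a bounded scalar maximization over log(lambda)
is numerically robust with no step-size tuning.

A region is *validated* when the |t| of its carrier indicator reaches the
threshold (2 by default) in the full population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .io import MISSING, GenotypeDataset


@dataclass(frozen=True)
class GRM:
    """Genomic relationship matrix plus the frequencies and scale used."""

    sample_ids: list
    matrix: np.ndarray
    allele_freqs: np.ndarray
    scale: float

    def submatrix(self, ids: Sequence[str]) -> np.ndarray:
        index = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([index[s] for s in ids])
        return self.matrix[np.ix_(idx, idx)]


def compute_grm(dataset: GenotypeDataset, marker_step: int = 1) -> GRM:
    """VanRaden method-1 GRM: G = W W' / (2 sum p(1-p)), W = M - 2p.

    Missing calls are mean-imputed per marker for this computation only.
    ``marker_step`` thins the marker panel (every k-th marker) when an
    approximate G is enough.
    """
    calls = dataset.calls[:, ::marker_step].astype(float)
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    mean = np.where(n_obs > 0, np.where(obs, calls, 0.0).sum(axis=0) / np.maximum(n_obs, 1), 0.0)
    calls = np.where(obs, calls, mean)
    p = mean / 2.0
    scale = float(2.0 * np.sum(p * (1.0 - p)))
    if scale <= 0:
        raise ValueError("all markers monomorphic; GRM scale is zero")
    W = calls - 2.0 * p
    G = (W @ W.T) / scale
    return GRM(
        sample_ids=list(dataset.sample_ids),
        matrix=G,
        allele_freqs=p,
        scale=scale,
    )


@dataclass
class GBLUPResults:
    """Estimates from a fitted GBLUP model (statsmodels-style results)."""

    model: "GBLUPModel"
    params: np.ndarray
    bse: np.ndarray
    sigma_g2: float
    sigma_e2: float
    converged: bool
    n_iter: int
    method: str
    loglike_reml: float | None = None
    _u_hat: np.ndarray | None = field(default=None, repr=False)

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.bse > 0, self.params / self.bse, np.nan)

    @property
    def pvalues(self) -> np.ndarray:
        df = max(self.model.nobs - self.model.exog.shape[1], 1)
        return 2.0 * sps.t.sf(np.abs(self.tvalues), df)

    @property
    def heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else np.nan

    @property
    def u_hat(self) -> np.ndarray:
        """BLUPs of the animal genetic effects for the phenotyped samples."""
        if self._u_hat is None:
            m = self.model
            V = self.sigma_g2 * m.H + self.sigma_e2 * np.eye(m.nobs)
            resid = m.endog - m.exog @ self.params
            self._u_hat = self.sigma_g2 * m.H @ np.linalg.solve(V, resid)
        return self._u_hat

    def summary(self) -> str:
        lines = [
            "GBLUP mixed model results",
            "=" * 60,
            f"n obs: {self.model.nobs:>6d}    method: {self.method}",
            f"sigma_g2: {self.sigma_g2:.6g}    sigma_e2: {self.sigma_e2:.6g}",
            f"h2: {self.heritability:.4f}    converged: {self.converged}"
            f"    iterations: {self.n_iter}",
            "-" * 60,
            f"{'effect':<12}{'estimate':>12}{'std err':>12}{'t':>10}{'P>|t|':>12}",
        ]
        names = self.model.exog_names
        for name, b, se, t, p in zip(names, self.params, self.bse, self.tvalues, self.pvalues):
            lines.append(f"{name:<12}{b:>12.5g}{se:>12.5g}{t:>10.3f}{p:>12.3g}")
        lines.append("=" * 60)
        return "\n".join(lines)


class GBLUPModel:
    """Single-trait GBLUP model of a phenotype on fixed effects plus an
    animal genetic effect with GRM covariance.

    Parameters
    ----------
    endog : (n,) phenotype vector.
    exog : (n, p) fixed-effect design (include the intercept column).
    grm : GRM for a superset of the phenotyped samples.
    sample_ids : ids aligning rows of ``endog`` to the GRM; defaults to the
        GRM's own order (requiring matching length).
    exog_names : column labels for reporting.
    """

    def __init__(self, endog, exog, grm: GRM, sample_ids=None, exog_names=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        self.exog = exog
        n, p = exog.shape
        if len(self.endog) != n:
            raise ValueError("endog and exog lengths differ")
        if np.linalg.matrix_rank(exog) < p:
            raise ValueError("fixed-effect design matrix is rank deficient")
        if sample_ids is None:
            if n != len(grm.sample_ids):
                raise ValueError("sample_ids required when phenotypes are a subset")
            sample_ids = list(grm.sample_ids)
        self.sample_ids = list(sample_ids)
        self.grm = grm
        self.H = grm.submatrix(self.sample_ids)  # Z G Z'
        self.exog_names = list(exog_names) if exog_names else [f"x{j}" for j in range(p)]
        self._eig: tuple | None = None

    @property
    def nobs(self) -> int:
        return len(self.endog)

    # -- internals ---------------------------------------------------------

    def _eigendecompose(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        if self._eig is None:
            d, U = np.linalg.eigh(self.H)
            d = np.clip(d, 0.0, None)
            self._eig = (d, U, U.T @ self.endog, U.T @ self.exog)
        return self._eig

    def _profile_reml(self, log_lambda: float) -> tuple[float, np.ndarray, np.ndarray, float]:
        """Minus twice the REML log-likelihood profiled over scale, plus the
        GLS estimates at this variance ratio."""
        d, _, yt, Xt = self._eigendecompose()
        lam = np.exp(log_lambda)
        v = lam * d + 1.0
        w = 1.0 / v
        XtWX = Xt.T @ (Xt * w[:, None])
        XtWy = Xt.T @ (yt * w)
        b = np.linalg.solve(XtWX, XtWy)
        resid = yt - Xt @ b
        rss = float(resid @ (resid * w))
        n, p = Xt.shape
        sigma_e2 = rss / (n - p)
        sign, logdet_XtWX = np.linalg.slogdet(XtWX)
        m2ll = (
            (n - p) * np.log(sigma_e2)
            + float(np.sum(np.log(v)))
            + logdet_XtWX
            + (n - p)
        )
        return m2ll, b, XtWX, sigma_e2

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        sigma_g2: float | None = None,
        sigma_e2: float | None = None,
        log_lambda_bounds: tuple[float, float] = (-12.0, 12.0),
        tol: float = 1e-8,
        max_iter: int = 200,
    ) -> GBLUPResults:
        """Fit by REML (default) or with both variance components fixed."""
        if (sigma_g2 is None) != (sigma_e2 is None):
            raise ValueError("fix both variance components or neither")
        if sigma_g2 is not None:
            return self._fit_fixed(sigma_g2, sigma_e2, method="fixed", n_iter=0, converged=True)

        res = optimize.minimize_scalar(
            lambda t: self._profile_reml(t)[0],
            bounds=log_lambda_bounds,
            method="bounded",
            options={"xatol": tol, "maxiter": max_iter},
        )
        log_lam = float(res.x)
        m2ll, _, _, sig_e = self._profile_reml(log_lam)
        # a boundary solution at the lower bound means sigma_g2 ~ 0
        m2ll_zero, _, _, sig_e0 = self._profile_reml(log_lambda_bounds[0])
        if m2ll_zero <= m2ll:
            log_lam, m2ll, sig_e = log_lambda_bounds[0], m2ll_zero, sig_e0
        lam = np.exp(log_lam)
        out = self._fit_fixed(
            lam * sig_e,
            sig_e,
            method="reml",
            n_iter=int(res.nfev),
            converged=bool(res.success),
        )
        out.loglike_reml = -0.5 * m2ll
        return out

    def _fit_fixed(
        self, sigma_g2: float, sigma_e2: float, method: str, n_iter: int, converged: bool
    ) -> GBLUPResults:
        if sigma_g2 < 0 or sigma_e2 <= 0:
            raise ValueError("need sigma_g2 >= 0 and sigma_e2 > 0")
        d, U, yt, Xt = self._eigendecompose()
        v = sigma_g2 * d + sigma_e2
        w = 1.0 / v
        XtVX = Xt.T @ (Xt * w[:, None])
        XtVy = Xt.T @ (yt * w)
        cov_b = np.linalg.inv(XtVX)
        b = cov_b @ XtVy
        return GBLUPResults(
            model=self,
            params=b,
            bse=np.sqrt(np.diag(cov_b)),
            sigma_g2=float(sigma_g2),
            sigma_e2=float(sigma_e2),
            converged=converged,
            n_iter=n_iter,
            method=method,
        )


def fit_mixed_model(y, X, grm: GRM, variance_mode="reml", sample_ids=None, exog_names=None):
    """Functional wrapper: ``variance_mode`` is ``"reml"`` or a tuple
    ``(sigma_g2, sigma_e2)`` of fixed variance components."""
    model = GBLUPModel(y, X, grm, sample_ids=sample_ids, exog_names=exog_names)
    if variance_mode == "reml":
        return model.fit()
    sg, se = variance_mode
    return model.fit(sigma_g2=sg, sigma_e2=se)


def region_carrier_indicator(region, roh_set, sample_ids: Sequence[str]) -> np.ndarray:
    """1 where one of the sample's ROH covers the whole region, else 0."""
    carriers = region.carrier_ids
    return np.array([1.0 if s in carriers else 0.0 for s in sample_ids])


def validate_regions(
    regions,
    roh_set,
    phenotypes: pd.DataFrame,
    grm: GRM,
    t_threshold: float = 2.0,
    variance_mode="reml",
    joint: bool = False,
) -> pd.DataFrame:
    """Fit the GBLUP model per region (default) or jointly and flag regions
    whose carrier-indicator |t| reaches ``t_threshold``.

    ``phenotypes`` needs columns ``sample_id`` and ``scr``.  Regions where
    every phenotyped animal (or none) is a carrier are skipped with a warning.
    """
    pheno = phenotypes.drop_duplicates("sample_id").set_index("sample_id")["scr"]
    ids = [s for s in pheno.index if s in set(grm.sample_ids)]
    y = pheno.loc[ids].to_numpy(dtype=float)
    n = len(ids)
    usable, indicators = [], []
    rows = []
    for region in regions:
        z = region_carrier_indicator(region, roh_set, ids)
        if z.sum() in (0, n):
            warnings.warn(
                f"region {region.chromosome}:{region.start_bp}-{region.end_bp} "
                "is carried by all or none of the phenotyped samples; skipped"
            )
            rows.append((region, np.nan, np.nan, np.nan, np.nan, np.nan, False, True))
            continue
        usable.append(region)
        indicators.append(z)

    def _row(region, res, j):
        b, se, t = res.params[j], res.bse[j], res.tvalues[j]
        return (
            region,
            float(b),
            float(se),
            float(t),
            float(res.sigma_g2),
            float(res.sigma_e2),
            bool(abs(t) >= t_threshold),
            False,
        )

    if usable and joint:
        X = np.column_stack([np.ones(n)] + indicators)
        names = ["intercept"] + [
            f"roh_{r.chromosome}_{r.start_bp}" for r in usable
        ]
        res = fit_mixed_model(y, X, grm, variance_mode, sample_ids=ids, exog_names=names)
        for j, region in enumerate(usable, start=1):
            rows.append(_row(region, res, j))
    else:
        for region, z in zip(usable, indicators):
            X = np.column_stack([np.ones(n), z])
            res = fit_mixed_model(
                y, X, grm, variance_mode, sample_ids=ids, exog_names=["intercept", "carrier"]
            )
            rows.append(_row(region, res, 1))

    rows.sort(key=lambda r: (r[0].chromosome, r[0].start_bp))
    return pd.DataFrame(
        [
            (
                r[0].chromosome,
                r[0].start_bp,
                r[0].end_bp,
                len(r[0].carrier_ids),
                r[1],
                r[2],
                r[3],
                r[4],
                r[5],
                r[6],
                r[7],
            )
            for r in rows
        ],
        columns=[
            "chromosome",
            "start_bp",
            "end_bp",
            "n_carriers",
            "beta",
            "se",
            "t_value",
            "sigma_g2",
            "sigma_e2",
            "validated",
            "skipped",
        ],
    )
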