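"""Domain types, dataset I/O, laterality recoding, standardization and configuration.

The central container is :class:`ROIDataset`: an ``n x R`` matrix of
standardized region-of-interest (ROI) intensities (z-score-like values,
positive = hypermetabolic relative to a healthy reference), a binary clinical
outcome per subject (1 = adverse event, e.g. not seizure-free), and an
optional matrix of baseline covariates.

All delimited files are CSV with a header row; the X/U/correlation files
carry the subject id (resp. region label) in the first column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ROIDataset",
    "Hyperparameters",
    "McmcSettings",
    "load_dataset",
    "write_dataset",
    "recode_laterality",
    "standardize_rois",
    "load_config",
]


class DataValidationError(ValueError):
    """Raised when an input file or array violates the dataset contract."""


@dataclass(frozen=True)
class ROIDataset:
    """Subjects x regions intensities with outcomes and optional covariates.

    Attributes
    ----------
    X : (n, R) float array of standardized ROI intensities.
    Y : (n,) int array with entries in {0, 1}; 1 codes the adverse event.
    U : (n, q) float array of baseline covariates; q may be 0.
    region_labels : length-R unique strings.
    subject_ids : length-n strings.
    """

    X: np.ndarray
    Y: np.ndarray
    U: np.ndarray
    region_labels: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        Y = np.asarray(self.Y)
        U = np.asarray(self.U, dtype=float)
        if X.ndim != 2:
            raise DataValidationError("X must be a 2-D matrix")
        n, R = X.shape
        if n < 2 or R < 2:
            raise DataValidationError(f"need n >= 2 subjects and R >= 2 regions, got {X.shape}")
        if not np.all(np.isfinite(X)):
            raise DataValidationError("X contains non-finite entries")
        if Y.shape != (n,):
            raise DataValidationError(f"Y has shape {Y.shape}, expected ({n},)")
        bad = sorted(set(np.unique(Y)) - {0, 1})
        if bad:
            raise DataValidationError(f"Y must be binary in {{0,1}}; offending values: {bad}")
        if U.size == 0:
            U = np.zeros((n, 0))
        if U.ndim != 2 or U.shape[0] != n:
            raise DataValidationError(f"U has shape {U.shape}, expected ({n}, q)")
        if not np.all(np.isfinite(U)):
            raise DataValidationError("U contains non-finite entries")
        if len(self.region_labels) != R:
            raise DataValidationError("region_labels length does not match X columns")
        if len(set(self.region_labels)) != R:
            raise DataValidationError("region_labels must be unique")
        if len(self.subject_ids) != n:
            raise DataValidationError("subject_ids length does not match X rows")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "Y", Y.astype(int))
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "region_labels", tuple(str(r) for r in self.region_labels))
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def R(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.U.shape[1]


@dataclass(frozen=True)
class Hyperparameters:
    """Prior hyperparameters of the hierarchical model.

    Defaults follow the reference analysis configuration: vague Dirichlet
    weights (alpha_k = 1), Ising sparsity e = -4.5 (a >= 1% marginal prior
    selection probability for isolated regions), smoothness f = 0.1, ICAR
    unscaled variance c_k = 5, IG(2, 1) variance priors, and a N(0, 5 I)
    prior on the logistic coefficients.
    """

    K: int = 2
    alpha: np.ndarray | None = None
    e: float = -4.5
    f: float = 0.1
    c_k: float = 5.0
    a_k: float = 2.0
    b_k: float = 1.0
    a_0: float = 2.0
    b_0: float = 1.0
    m_beta: np.ndarray | None = None
    V_beta: np.ndarray | None = None
    beta_prior_scale: float = 5.0

    def __post_init__(self) -> None:
        if self.K < 2:
            raise ValueError("K must be >= 2")
        alpha = np.ones(self.K) if self.alpha is None else np.asarray(self.alpha, dtype=float)
        if alpha.shape != (self.K,) or np.any(alpha <= 0):
            raise ValueError("alpha must be length-K and positive")
        for name in ("c_k", "a_k", "b_k", "a_0", "b_0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.f < 0:
            raise ValueError("f must be >= 0")
        object.__setattr__(self, "alpha", alpha)

    def beta_prior(self, q: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (m_beta, V_beta) for a coefficient vector of length K + q.

        The coefficient vector is (beta_0, beta_1, ..., beta_{K-1}, beta_U)
        with state K as the reference.
        """
        p = self.K + q
        m = np.zeros(p) if self.m_beta is None else np.asarray(self.m_beta, dtype=float)
        if self.V_beta is None:
            V = self.beta_prior_scale * np.eye(p)
        else:
            V = np.asarray(self.V_beta, dtype=float)
        if m.shape != (p,):
            raise ValueError(f"m_beta must have length {p}")
        if V.shape != (p, p) or not np.allclose(V, V.T):
            raise ValueError("V_beta must be symmetric (p, p)")
        if np.any(np.linalg.eigvalsh(V) <= 0):
            raise ValueError("V_beta must be positive definite")
        return m, V


@dataclass(frozen=True)
class McmcSettings:
    """Chain length, burn-in, thinning, seeding and initialization rules.

    Defaults mirror the reference analysis: 100,000 sweeps with the first
    50,000 discarded, two chains started from different numbers of selected
    regions and different subject allocations. Scale ``n_iter``/``burn_in``
    down for exploratory runs.
    """

    n_iter: int = 100_000
    burn_in: int = 50_000
    n_chains: int = 2
    thin: int = 1
    seed: int = 0
    init_gamma_count: int | None = None
    init_allocation: str = "random"

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.init_allocation not in ("random", "kmeans"):
            raise ValueError("init_allocation must be 'random' or 'kmeans'")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def _read_csv(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"file not found: {path}")
    return pd.read_csv(path, index_col=index_col, float_precision="round_trip")


def load_dataset(
    x_path: str | Path,
    y_path: str | Path,
    u_path: str | Path | None = None,
) -> ROIDataset:
    """Load and validate an :class:`ROIDataset` from delimited text files.

    ``x_path``: CSV with subject ids in the first column and region labels as
    header. ``y_path``: CSV with subject ids and a single binary column.
    ``u_path``: optional CSV of covariates with subject ids.
    """
    xdf = _read_csv(x_path)
    ydf = _read_csv(y_path)
    if ydf.shape[1] != 1:
        raise DataValidationError(f"{y_path}: expected a single outcome column, got {ydf.shape[1]}")
    if xdf.shape[0] != ydf.shape[0]:
        raise DataValidationError(
            f"dimension mismatch: {x_path} has {xdf.shape[0]} rows but {y_path} has {ydf.shape[0]}"
        )
    yvals = ydf.iloc[:, 0].to_numpy()
    if not np.all(np.isin(yvals, (0, 1))):
        bad = sorted(set(yvals) - {0, 1})
        raise DataValidationError(f"{y_path}: outcome must be binary in {{0,1}}; offending values: {bad}")
    if u_path is not None:
        udf = _read_csv(u_path)
        if udf.shape[0] != xdf.shape[0]:
            raise DataValidationError(
                f"dimension mismatch: {x_path} has {xdf.shape[0]} rows but {u_path} has {udf.shape[0]}"
            )
        U = udf.to_numpy(dtype=float)
    else:
        U = np.zeros((xdf.shape[0], 0))
    if not np.all(np.isfinite(xdf.to_numpy(dtype=float))):
        raise DataValidationError(f"{x_path}: non-finite entries")
    return ROIDataset(
        X=xdf.to_numpy(dtype=float),
        Y=yvals.astype(int),
        U=U,
        region_labels=tuple(map(str, xdf.columns)),
        subject_ids=tuple(map(str, xdf.index)),
    )


def write_dataset(dataset: ROIDataset, x_path: str | Path, y_path: str | Path,
                  u_path: str | Path | None = None) -> None:
    """Write a dataset back to the CSV dialect accepted by :func:`load_dataset`."""
    idx = pd.Index(dataset.subject_ids, name="subject")
    pd.DataFrame(dataset.X, index=idx, columns=list(dataset.region_labels)).to_csv(x_path)
    pd.DataFrame({"outcome": dataset.Y}, index=idx).to_csv(y_path)
    if u_path is not None:
        cols = [f"u{j}" for j in range(dataset.q)]
        pd.DataFrame(dataset.U, index=idx, columns=cols).to_csv(u_path)


def recode_laterality(
    dataset: ROIDataset,
    side: Sequence[str],
    pair_map: Mapping[str, str],
) -> ROIDataset:
    """Recode lateralized region columns from left/right to ipsi/contralateral.

    ``side[i]`` is the side of pathology ("left" or "right") for subject i.
    ``pair_map`` maps each left-region label to its mirrored right-region
    label. For right-sided subjects the paired columns are swapped so that
    every left-labeled column reads as ipsilateral and every right-labeled
    column as contralateral; midline (unpaired) regions are untouched.
    """
    if len(side) != dataset.n:
        raise DataValidationError("side must have one entry per subject")
    labels = list(dataset.region_labels)
    pairs: list[tuple[int, int]] = []
    for left, right in pair_map.items():
        if left not in labels:
            raise DataValidationError(f"pair_map region {left!r} missing from region labels")
        if right not in labels:
            raise DataValidationError(f"pair_map region {right!r} missing from region labels")
        pairs.append((labels.index(left), labels.index(right)))
    X = dataset.X.copy()
    for i, s in enumerate(side):
        if s not in ("left", "right"):
            raise DataValidationError(f"side[{i}] must be 'left' or 'right', got {s!r}")
        if s == "right":
            for a, b in pairs:
                X[i, a], X[i, b] = X[i, b], X[i, a]
    return replace(dataset, X=X)


def standardize_rois(raw: np.ndarray, ref_mean: np.ndarray, ref_sd: np.ndarray) -> np.ndarray:
    """Z-score raw ROI values against reference (healthy-control) moments."""
    raw = np.asarray(raw, dtype=float)
    ref_mean = np.asarray(ref_mean, dtype=float)
    ref_sd = np.asarray(ref_sd, dtype=float)
    if np.any(ref_sd <= 0):
        raise DataValidationError("ref_sd must be strictly positive elementwise")
    return (raw - ref_mean) / ref_sd


def load_config(path: str | Path) -> tuple[Hyperparameters, McmcSettings]:
    """Read hyperparameters and MCMC settings from a YAML (or JSON) file.

    Recognized top-level keys are ``hyperparameters`` and ``mcmc``; fields
    omitted from the file keep their dataclass defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    hp_kwargs = dict(cfg.get("hyperparameters", {}))
    for key in ("alpha", "m_beta"):
        if key in hp_kwargs and hp_kwargs[key] is not None:
            hp_kwargs[key] = np.asarray(hp_kwargs[key], dtype=float)
    if hp_kwargs.get("V_beta") is not None:
        hp_kwargs["V_beta"] = np.asarray(hp_kwargs["V_beta"], dtype=float)
    hyper = Hyperparameters(**hp_kwargs)
    settings = McmcSettings(**cfg.get("mcmc", {}))
    return hyper, settings
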