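"""The Gaussian host model.

A single multivariate normal density is fitted to the virus-minus-host
k-mer frequency difference vectors of known interactions. The host score of
a candidate (virus, host) pair is the log-density of its difference vector
under that normal — higher means more compatible. With one component this is
the closed-form fixed point of expectation-maximization for a Gaussian
mixture, so no iterative fitting is needed:

    mean       = column means of the training matrix
    covariance = (1/n) * Xc' Xc  +  reg_covar * I        (ML estimate)
    score(x)   = -0.5 * [ d*ln(2*pi) + ln|Sigma| + (x-mu)' Sigma^-1 (x-mu) ]

Difference vectors sum to zero by construction, so the unregularized
covariance is singular; ``reg_covar`` (default 1e-6 on the diagonal) is
mandatory, not cosmetic. Scores are natural-log densities used for ranking
and thresholding only; they are never normalized into probabilities across
candidate hosts.
"""

from __future__ import annotations

import json
import time
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .errors import (
    EmptyTrainingError,
    InvalidInputError,
    ModelFormatError,
    SingularModelError,
)
from .features import build_training_matrix
from .kmers import ProfileStore

_LOG_2PI = float(np.log(2.0 * np.pi))
_FORMAT_VERSION = 1


class VirusHostGaussian:
    """Gaussian host-compatibility model over difference-vector features.

    Parameters
    ----------
    features : ndarray of shape (n_pairs, d)
        One virus-minus-host difference vector per known interaction.
    k : int, optional
        k-mer length behind the features (d = 4**k); kept for provenance
        and validated on save/load when given.
    row_index : list of (virus_id, host_genome_id), optional
        Identity of each training row.
    """

    def __init__(
        self,
        features: np.ndarray,
        k: int | None = None,
        row_index: list[tuple[str, str]] | None = None,
    ):
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2:
            raise InvalidInputError(
                f"training matrix must be 2-D, got shape {features.shape}"
            )
        if k is not None and features.shape[1] != 4 ** int(k):
            raise InvalidInputError(
                f"feature dimension {features.shape[1]} != 4**{k}"
            )
        self.features = features
        self.k = None if k is None else int(k)
        self.row_index = row_index
        self.nobs, self.d = features.shape

    @classmethod
    def from_interactions(
        cls,
        interactions: pd.DataFrame,
        virus_profiles: ProfileStore,
        host_profiles: ProfileStore,
    ) -> "VirusHostGaussian":
        """Build the model from an interaction table and k-mer profile stores."""
        X, index = build_training_matrix(interactions, virus_profiles, host_profiles)
        return cls(X, k=virus_profiles.k, row_index=index)

    def fit(
        self, reg_covar: float = 1e-6, label: str | None = None
    ) -> "VirusHostGaussianResults":
        """Fit by the closed-form one-component maximum-likelihood estimate.

        ``reg_covar`` is added to the covariance diagonal before
        factorization; the n=1 edge case yields covariance = reg_covar * I.
        """
        if self.nobs == 0:
            raise EmptyTrainingError("cannot fit a Gaussian model on zero interactions")
        if reg_covar < 0:
            raise InvalidInputError(f"reg_covar must be >= 0, got {reg_covar}")
        mean = self.features.mean(axis=0)
        centered = self.features - mean
        covariance = centered.T @ centered / self.nobs
        covariance[np.diag_indices(self.d)] += reg_covar
        metadata = {
            "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "training_label": label or "",
        }
        return VirusHostGaussianResults(
            mean=mean,
            covariance=covariance,
            reg_covar=float(reg_covar),
            k=self.k,
            n_train=self.nobs,
            metadata=metadata,
            model=self,
        )


class VirusHostGaussianResults:
    """Fitted Gaussian host model: parameters, cached factorization, scoring."""

    def __init__(
        self,
        mean: np.ndarray,
        covariance: np.ndarray,
        reg_covar: float,
        k: int | None,
        n_train: int,
        metadata: dict | None = None,
        model: VirusHostGaussian | None = None,
    ):
        self.mean = np.asarray(mean, dtype=np.float64)
        self.covariance = np.asarray(covariance, dtype=np.float64)
        self.d = self.mean.shape[0]
        if self.covariance.shape != (self.d, self.d):
            raise InvalidInputError(
                f"covariance shape {self.covariance.shape} incompatible with d={self.d}"
            )
        asym = np.abs(self.covariance - self.covariance.T).max() if self.d else 0.0
        if asym > 1e-10:
            raise InvalidInputError(
                f"covariance not symmetric (max asymmetry {asym:.2e})"
            )
        self.reg_covar = float(reg_covar)
        self.k = None if k is None else int(k)
        self.n_train = int(n_train)
        self.metadata = dict(metadata or {})
        self.model = model
        try:
            self._chol = np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError:
            raise SingularModelError(
                "covariance is not positive definite even after adding "
                f"reg_covar={self.reg_covar:g}; increase reg_covar"
            ) from None
        self.log_det_cov = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    # -- scoring ---------------------------------------------------------

    def mahalanobis_sq(self, x: np.ndarray) -> float:
        """Squared Mahalanobis distance of one feature vector to the mean."""
        z = solve_triangular(self._chol, np.asarray(x, float) - self.mean, lower=True)
        return float(z @ z)

    def log_score(self, x: np.ndarray) -> float:
        """Log-density of one difference vector under the fitted normal."""
        x = np.asarray(x, dtype=np.float64)
        if x.shape != (self.d,):
            raise InvalidInputError(f"expected vector of length {self.d}, got {x.shape}")
        return -0.5 * (self.d * _LOG_2PI + self.log_det_cov + self.mahalanobis_sq(x))

    def log_score_batch(self, X: np.ndarray) -> np.ndarray:
        """Log-density for each row of an (n, d) matrix of difference vectors."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.d:
            raise InvalidInputError(
                f"expected matrix of shape (n, {self.d}), got {X.shape}"
            )
        Z = solve_triangular(self._chol, (X - self.mean).T, lower=True)
        maha = np.einsum("ij,ij->j", Z, Z)
        return -0.5 * (self.d * _LOG_2PI + self.log_det_cov + maha)

    def rank_hosts(self, virus_profile, catalog):
        """Rank every catalog host for one query virus (see phagehost.predict)."""
        from .predict import rank_hosts

        return rank_hosts(self, virus_profile, catalog)

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write the fitted model to an ``.npz`` container.

        Layout (format_version 1): a NumPy ``.npz`` archive with arrays
        ``format_version`` (int64 scalar), ``k`` (int64 scalar, -1 if
        unspecified), ``d`` (int64 scalar), ``reg_covar`` (float64 scalar),
        ``n_train`` (int64 scalar), ``mean`` (float64, shape (d,)),
        ``covariance`` (float64, shape (d, d), row-major) and
        ``metadata_json`` (unicode scalar). Full float64 precision is
        preserved, so a load/save round trip reproduces scores bit for bit.
        """
        with open(path, "wb") as fh:
            np.savez(
                fh,
                format_version=np.int64(_FORMAT_VERSION),
                k=np.int64(-1 if self.k is None else self.k),
                d=np.int64(self.d),
                reg_covar=np.float64(self.reg_covar),
                n_train=np.int64(self.n_train),
                mean=self.mean,
                covariance=self.covariance,
                metadata_json=np.str_(json.dumps(self.metadata)),
            )

    @classmethod
    def load(cls, path: str | Path) -> "VirusHostGaussianResults":
        try:
            with np.load(path, allow_pickle=False) as archive:
                version = int(archive["format_version"])
                if version != _FORMAT_VERSION:
                    raise ModelFormatError(f"unsupported format_version {version}")
                k = int(archive["k"])
                d = int(archive["d"])
                if k != -1 and d != 4**k:
                    raise ModelFormatError(f"inconsistent model file: d={d} != 4**{k}")
                mean = archive["mean"]
                covariance = archive["covariance"]
                if mean.shape != (d,) or covariance.shape != (d, d):
                    raise ModelFormatError(
                        f"inconsistent shapes: mean {mean.shape}, "
                        f"covariance {covariance.shape}, d={d}"
                    )
                return cls(
                    mean=mean,
                    covariance=covariance,
                    reg_covar=float(archive["reg_covar"]),
                    k=None if k == -1 else k,
                    n_train=int(archive["n_train"]),
                    metadata=json.loads(str(archive["metadata_json"])),
                )
        except ModelFormatError:
            raise
        except (OSError, KeyError, ValueError, zipfile.BadZipFile, EOFError) as exc:
            raise ModelFormatError(f"cannot read model file {path}: {exc}") from exc

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the fitted model."""
        var = np.diag(self.covariance)
        lines = [
            "Gaussian host model",
            "=" * 46,
            f"{'feature dim (d)':<28}{self.d}",
            f"{'k-mer length (k)':<28}{self.k if self.k is not None else 'n/a'}",
            f"{'training pairs (n)':<28}{self.n_train}",
            f"{'reg_covar':<28}{self.reg_covar:g}",
            f"{'log|covariance|':<28}{self.log_det_cov:.6g}",
            f"{'mean: max |entry|':<28}{np.abs(self.mean).max():.3e}",
            f"{'diag variance: min / max':<28}{var.min():.3e} / {var.max():.3e}",
            f"{'training label':<28}{self.metadata.get('training_label', '') or '-'}",
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<VirusHostGaussianResults d={self.d} k={self.k} "
            f"n_train={self.n_train} reg_covar={self.reg_covar:g}>"
        )
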