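"""Independent component analysis of EEG and the component-zeroing baseline.

The recorded channels X(t) are modelled as an instantaneous linear mixture
X = M s of statistically independent sources s.  FastICA (log-cosh
contrast, symmetric decorrelation) estimates M and s; the conventional
artifact-removal baseline then zeroes whole artifact components and remixes
(X_hat = M s_hat).  Channel means are removed before whitening and restored
on every reconstruction.

Component order and sign are arbitrary and change between runs, so all
comparisons here match components to references by maximal absolute
correlation, and the ranking helper returns an explicit ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .preproc import Recording


class ICAError(ValueError):
    """Raised for invalid decompositions or decomposition requests."""


@dataclass
class ICADecomposition:
    """Result of FastICA on one recording.

    ``mixing @ sources + mean[:, None]`` reproduces the input (exactly, for
    a square model).  ``sources`` have unit variance; ``unmixing`` maps
    centered channels to sources.
    """

    mixing: np.ndarray  # (n_channels, n_components)
    unmixing: np.ndarray  # (n_components, n_channels)
    sources: np.ndarray  # (n_components, n_samples)
    mean: np.ndarray  # per-channel mean removed before whitening
    converged: bool
    n_iter: int
    fs: float
    channel_labels: list[str]

    @property
    def n_components(self) -> int:
        return self.sources.shape[0]


def fastica_decompose(
    rec: Recording,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> ICADecomposition:
    """Run FastICA on a recording.

    Defaults to a square model (``n_components = n_channels``).  The
    ``converged`` flag honestly reports whether the tolerance was reached
    within ``max_iter`` sweeps; non-convergence is a warning, not an error.
    """
    n_components = rec.n_channels if n_components is None else n_components
    if n_components > rec.n_channels:
        raise ICAError(
            f"n_components={n_components} exceeds n_channels={rec.n_channels}"
        )
    if rec.n_samples < 20 * rec.n_channels**2:
        warnings.warn(
            f"only {rec.n_samples} samples for {rec.n_channels} channels; "
            "ICA estimates may be unstable (rule of thumb: 20 x n_channels^2)",
            stacklevel=2,
        )
    x = rec.data
    cov_eigs = np.linalg.eigvalsh(np.cov(x))
    if cov_eigs[0] <= 1e-12 * max(cov_eigs[-1], 1e-30):
        raise ICAError(
            "input is rank deficient after whitening; reduce n_components "
            f"below {int(np.sum(cov_eigs > 1e-12 * cov_eigs[-1]))}"
        )

    ica = FastICA(
        n_components=n_components,
        algorithm="parallel",
        fun="logcosh",
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(x.T).T
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            converged = False
        else:
            warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)
    if not converged:
        warnings.warn(
            f"FastICA did not converge within {max_iter} iterations (tol={tol})",
            stacklevel=2,
        )
    return ICADecomposition(
        mixing=ica.mixing_,
        unmixing=ica.components_,
        sources=sources,
        mean=ica.mean_,
        converged=converged,
        n_iter=int(ica.n_iter_),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
    )


def reconstruct(dec: ICADecomposition, sources: np.ndarray | None = None) -> Recording:
    """Remix sources (default: all of them) back into channel space."""
    s = dec.sources if sources is None else sources
    data = dec.mixing @ s + dec.mean[:, None]
    return Recording(
        data=data, fs=dec.fs, channel_labels=list(dec.channel_labels),
        reference="ICA reconstruction",
    )


def ica_zero_clean(dec: ICADecomposition, artifact_indices) -> Recording:
    """Conventional ICA cleaning: zero the listed components and remix.

    With an empty index set this returns the plain reconstruction of the
    input; zeroing every component leaves only the restored channel means.
    """
    artifact_indices = sorted(set(int(i) for i in artifact_indices))
    for i in artifact_indices:
        if not 0 <= i < dec.n_components:
            raise ICAError(
                f"component index {i} out of range [0, {dec.n_components})"
            )
    s_hat = dec.sources.copy()
    if artifact_indices:
        s_hat[artifact_indices, :] = 0.0
    rec = reconstruct(dec, s_hat)
    rec.reference = f"ICA-cleaned (zeroed components {artifact_indices})"
    return rec


@dataclass
class ComponentRanking:
    """Components ordered most-artifact-like first, with their scores."""

    order: list[int]
    scores: np.ndarray  # per component, aligned with decomposition order
    method: str  # "reference-correlation" | "kurtosis"
    low_confidence: bool


def rank_artifact_components(
    dec: ICADecomposition,
    reference: Recording | np.ndarray | None = None,
) -> ComponentRanking:
    """Order components by artifact likelihood.

    With a reference (e.g. a simulator's artifact-only tracks) each
    component is scored by its maximal absolute correlation with any
    reference channel.  Without one, the fallback is excess kurtosis:
    blink/burst transients are strongly super-Gaussian.  All-Gaussian
    decompositions (max excess kurtosis < 1) are flagged low-confidence.
    """
    if reference is not None:
        ref = reference.data if isinstance(reference, Recording) else np.atleast_2d(reference)
        if ref.shape[1] != dec.sources.shape[1]:
            raise ICAError("reference length does not match the decomposition")
        s = dec.sources - dec.sources.mean(axis=1, keepdims=True)
        r = ref - ref.mean(axis=1, keepdims=True)
        s_norm = np.linalg.norm(s, axis=1)
        r_norm = np.linalg.norm(r, axis=1)
        denom = np.outer(r_norm, s_norm)
        denom[denom == 0] = np.inf
        corr = np.abs(r @ s.T) / denom  # (n_ref, n_comp)
        scores = corr.max(axis=0)
        method = "reference-correlation"
        low_confidence = False
    else:
        scores = stats.kurtosis(dec.sources, axis=1, fisher=True)
        method = "kurtosis"
        low_confidence = bool(np.max(scores) < 1.0)
    order = list(np.argsort(-scores, kind="stable"))
    return ComponentRanking(
        order=order, scores=np.asarray(scores, dtype=float),
        method=method, low_confidence=low_confidence,
    )
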