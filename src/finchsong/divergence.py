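"""Song Divergence: a directional, tempo-independent song-learning score.

Each bird's song spectral content is modelled from a corpus of song bouts
(nominally 60): bouts are segmented into syllables, each syllable is reduced
to a single power spectral density (discarding within-syllable temporal
structure), PSDs are mapped into a syllable-syllable similarity space
(Pearson correlation against a random reference basis, then principal-axis
reduction), and a Gaussian mixture model is fitted to each bird's embedded
syllables. The Song Divergence (SD) is the Kullback-Leibler divergence, in
bits, from the tutor's mixture to the tutee's, estimated by Monte Carlo
sampling from the tutor model. SD is directional: it measures tutor
spectral content *missing* from the tutee ("missing content") and ignores
tutee content absent from the tutor ("improvisation"). SD = 0 means a
perfect copy; larger values mean progressively worse copies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.linalg import solve_triangular
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .audio import Waveform, amplitude_envelope, highpass
from .segmentation import SegmentationParams, segment_syllables
from .synth import SongCorpus

__all__ = [
    "PsdVector",
    "GmmModel",
    "SDScore",
    "DivergenceConfig",
    "syllable_psd",
    "corpus_psds",
    "build_basis",
    "similarity_embed",
    "SimilaritySpace",
    "fit_gmm",
    "gmm_kl_mc",
    "KlEstimate",
    "song_divergence",
]

MIN_BOUTS = 60
_LOG_EPS = 1e-12


@dataclass(frozen=True)
class DivergenceConfig:
    """Tunable settings for the SD pipeline.

    Welch PSDs use ``psd_nperseg``-sample windows with 50% overlap,
    restricted to the analysis band (Hz). ``basis_size`` reference syllables
    define the similarity space, reduced to ``n_dims`` whitened principal
    axes fitted on the pooled tutor+tutee syllables (whitening makes
    ``reg_covar`` a fraction of per-axis variance). The GMM component count
    is either a fixed integer or 'auto' (BIC scan over ``k_range``). The KL
    estimate uses ``mc_samples`` Monte-Carlo draws from the tutor model.
    ``reg_covar`` doubles as a density smoothing floor: it bounds how sharply
    either model can concentrate, which keeps the divergence of two
    independently fitted models of the *same* song near zero.
    """

    psd_nperseg: int = 512
    psd_overlap: float = 0.5
    band: tuple[float, float] = (500.0, 16000.0)
    basis_size: int = 50
    n_dims: int = 10
    k: int | str = "auto"
    k_range: tuple[int, int] = (2, 12)
    n_init: int = 5
    reg_covar: float = 0.05
    mc_samples: int = 100_000
    seed: int = 0
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)


@dataclass(frozen=True)
class PsdVector:
    """Unit-sum power over a fixed in-band frequency grid (Hz)."""

    power: np.ndarray
    freqs: np.ndarray

    def __post_init__(self):
        power = np.asarray(self.power, dtype=np.float64)
        freqs = np.asarray(self.freqs, dtype=np.float64)
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "freqs", freqs)
        if power.shape != freqs.shape:
            raise ValueError("power and freqs must align")
        if np.any(power < 0):
            raise ValueError("power must be non-negative")

    @property
    def log_power(self) -> np.ndarray:
        return np.log10(self.power + _LOG_EPS)


def syllable_psd(
    w: Waveform, config: DivergenceConfig | None = None
) -> PsdVector:
    """Welch PSD of one syllable slice, band-restricted and unit-sum normalized.

    Raises ValueError for slices shorter than one analysis window.
    """
    cfg = config or DivergenceConfig()
    if w.samples.size < cfg.psd_nperseg:
        raise ValueError(
            f"slice of {w.samples.size} samples is shorter than one "
            f"{cfg.psd_nperseg}-sample analysis window"
        )
    freqs, power = sps.welch(
        w.samples,
        fs=w.rate,
        nperseg=cfg.psd_nperseg,
        noverlap=int(cfg.psd_nperseg * cfg.psd_overlap),
    )
    lo, hi = cfg.band
    keep = (freqs >= lo) & (freqs <= hi)
    power = power[keep]
    total = power.sum()
    if total <= 0:
        raise ValueError("no power in the analysis band")
    return PsdVector(power / total, freqs[keep])


def corpus_psds(
    corpus: SongCorpus, config: DivergenceConfig | None = None
) -> list[PsdVector]:
    """Segment every bout of a corpus and compute one PSD per syllable.

    Slices shorter than one analysis window (possible for heavily corrupted
    or truncated syllables) are skipped.
    """
    cfg = config or DivergenceConfig()
    out: list[PsdVector] = []
    for bout in corpus.bouts:
        filtered = highpass(bout.waveform)
        env = amplitude_envelope(filtered)
        for interval in segment_syllables(env, cfg.segmentation):
            i0 = int(interval.onset * filtered.rate)
            i1 = int(interval.offset * filtered.rate)
            if i1 - i0 < cfg.psd_nperseg:
                continue
            out.append(
                syllable_psd(Waveform(filtered.samples[i0:i1], filtered.rate), cfg)
            )
    return out


def build_basis(
    psds: list[PsdVector], n_basis: int, seed: int
) -> list[PsdVector]:
    """Sample ``n_basis`` reference PSDs without replacement (seeded)."""
    if n_basis > len(psds):
        raise ValueError(f"basis size {n_basis} exceeds {len(psds)} syllables")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(psds), size=n_basis, replace=False)
    return [psds[i] for i in idx]


def _similarity_matrix(psds: list[PsdVector], basis: list[PsdVector]) -> np.ndarray:
    """Pearson correlation of log-power spectra against each basis member."""
    if any(b.freqs.shape != psds[0].freqs.shape for b in basis):
        raise ValueError("frequency grid mismatch between PSDs and basis")
    X = np.vstack([p.log_power for p in psds])
    B = np.vstack([b.log_power for b in basis])
    X = X - X.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(X, axis=1, keepdims=True)
    bn = np.linalg.norm(B, axis=1, keepdims=True)
    xn[xn == 0] = 1.0
    bn[bn == 0] = 1.0
    return (X / xn) @ (B / bn).T


def similarity_embed(psd: PsdVector, basis: list[PsdVector]) -> np.ndarray:
    """Coordinates of one syllable in similarity space (correlation to each
    basis member); dimensionality reduction is handled by SimilaritySpace."""
    return _similarity_matrix([psd], basis)[0]


class SimilaritySpace:
    """Random-basis similarity embedding with principal-axis reduction.

    Fitted once on the pooled tutor+tutee syllables so both birds share one
    coordinate system; ``transform`` then maps any PSD list into d dimensions.
    """

    def __init__(self, basis: list[PsdVector], pca: PCA):
        self.basis = basis
        self.pca = pca

    @classmethod
    def fit(
        cls, psds: list[PsdVector], config: DivergenceConfig | None = None
    ) -> "SimilaritySpace":
        cfg = config or DivergenceConfig()
        basis = build_basis(psds, cfg.basis_size, cfg.seed)
        sims = _similarity_matrix(psds, basis)
        n_dims = min(cfg.n_dims, sims.shape[0], sims.shape[1])
        pca = PCA(n_components=n_dims, whiten=True, random_state=cfg.seed).fit(sims)
        return cls(basis, pca)

    def transform(self, psds: list[PsdVector]) -> np.ndarray:
        return self.pca.transform(_similarity_matrix(psds, self.basis))


@dataclass(frozen=True)
class GmmModel:
    """A Gaussian mixture density: simplex weights, component means, and
    symmetric positive-definite covariances."""

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        m = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        c = np.asarray(self.covariances, dtype=np.float64)
        if c.ndim == 2:  # per-component diagonal
            c = np.stack([np.diag(row) for row in c])
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", m)
        object.__setattr__(self, "covariances", c)
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        # Cholesky factors double as the SPD check
        object.__setattr__(self, "_chol", np.linalg.cholesky(c))

    @property
    def n_components(self) -> int:
        return self.weights.size

    @property
    def n_dims(self) -> int:
        return self.means.shape[1]

    def log_density(self, x: np.ndarray) -> np.ndarray:
        """Natural-log mixture density at each row of x."""
        x = np.atleast_2d(x)
        n, d = x.shape
        if d != self.n_dims:
            raise ValueError(f"dimension mismatch: {d} != {self.n_dims}")
        comp = np.empty((self.n_components, n))
        const = -0.5 * d * np.log(2 * np.pi)
        for j in range(self.n_components):
            L = self._chol[j]
            z = solve_triangular(L, (x - self.means[j]).T, lower=True)
            log_det = np.sum(np.log(np.diag(L)))
            comp[j] = const - log_det - 0.5 * np.sum(z ** 2, axis=0)
        return logsumexp(comp + np.log(self.weights)[:, None], axis=0)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        counts = rng.multinomial(n, self.weights)
        parts = []
        for j, nj in enumerate(counts):
            if nj == 0:
                continue
            z = rng.standard_normal((nj, self.n_dims))
            parts.append(self.means[j] + z @ self._chol[j].T)
        out = np.vstack(parts)
        return out[rng.permutation(n)]


def fit_gmm(
    points: np.ndarray,
    k: int | str = "auto",
    seed: int = 0,
    config: DivergenceConfig | None = None,
) -> GmmModel:
    """Fit a Gaussian mixture to embedded syllables.

    With k='auto' the component count is chosen by BIC over the configured
    range (capped so each component keeps a few points). Covariances are
    diagonal with a regularization floor; several EM restarts per k.
    Degenerate input (all points identical) raises with guidance.
    """
    cfg = config or DivergenceConfig()
    X = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if np.allclose(X, X[0]):
        raise ValueError(
            "degenerate data: all embedded syllables are identical; "
            "check segmentation and the similarity basis"
        )
    if k == "auto":
        lo, hi = cfg.k_range
        hi = min(hi, max(lo, X.shape[0] // 5))
        candidates = range(lo, hi + 1)
    else:
        candidates = [int(k)]
    best = None
    best_bic = np.inf
    for kk in candidates:
        gm = GaussianMixture(
            n_components=kk,
            covariance_type="diag",
            reg_covar=cfg.reg_covar,
            n_init=cfg.n_init,
            random_state=seed,
        ).fit(X)
        bic = gm.bic(X)
        if bic < best_bic:
            best_bic, best = bic, gm
    if not best.converged_:
        warnings.warn("GMM EM did not converge; consider more iterations")
    return GmmModel(best.weights_, best.means_, best.covariances_)


@dataclass(frozen=True)
class KlEstimate:
    """Monte-Carlo KL(p||q) in bits with its standard error; clamped at 0."""

    bits: float
    raw_bits: float
    stderr_bits: float
    n: int
    seed: int


def gmm_kl_mc(p: GmmModel, q: GmmModel, n: int, seed: int) -> KlEstimate:
    """Monte-Carlo estimate of KL(p||q) = E_p[log2 p(x) - log2 q(x)].

    Samples n points from p; the estimate is clamped at 0 (KL is
    non-negative; small negative estimates are Monte-Carlo noise).
    Directionality is preserved: in general KL(p,q) != KL(q,p).
    """
    if p.n_dims != q.n_dims:
        raise ValueError("dimension mismatch between mixtures")
    rng = np.random.default_rng(seed)
    x = p.sample(n, rng)
    ratios = (p.log_density(x) - q.log_density(x)) / np.log(2)
    raw = float(np.mean(ratios))
    stderr = float(np.std(ratios, ddof=1) / np.sqrt(n))
    return KlEstimate(max(raw, 0.0), raw, stderr, n, seed)


@dataclass(frozen=True)
class SDScore:
    """A Song Divergence result (tutor -> tutee direction, in bits)."""

    bits: float
    direction: str
    n_bouts_tutor: int
    n_bouts_tutee: int
    mc_samples: int
    seed: int
    stderr_bits: float
    low_bout_warning: bool


def song_divergence(
    tutor: SongCorpus,
    tutee: SongCorpus,
    config: DivergenceConfig | None = None,
) -> SDScore:
    """Full SD pipeline: segment both corpora, compute per-syllable PSDs,
    fit one shared similarity space on the pooled syllables, fit a GMM per
    bird, and estimate KL(tutor || tutee) in bits.

    Corpora below 60 bouts are scored but flagged. For computer-tutored
    cohorts, pass a designated well-learned reference corpus as ``tutor``
    (see :func:`finchsong.synth.generate_reference_corpus`).
    """
    cfg = config or DivergenceConfig()
    low = tutor.n_bouts < MIN_BOUTS or tutee.n_bouts < MIN_BOUTS
    if low:
        warnings.warn(
            f"corpus below {MIN_BOUTS} bouts "
            f"(tutor {tutor.n_bouts}, tutee {tutee.n_bouts}); SD is less stable"
        )
    psds_tutor = corpus_psds(tutor, cfg)
    psds_tutee = corpus_psds(tutee, cfg)
    if not psds_tutor or not psds_tutee:
        raise ValueError("a corpus yielded no analyzable syllables")
    space = SimilaritySpace.fit(psds_tutor + psds_tutee, cfg)
    gmm_tutor = fit_gmm(space.transform(psds_tutor), cfg.k, cfg.seed, cfg)
    gmm_tutee = fit_gmm(space.transform(psds_tutee), cfg.k, cfg.seed, cfg)
    kl = gmm_kl_mc(gmm_tutor, gmm_tutee, cfg.mc_samples, cfg.seed)
    return SDScore(
        bits=kl.bits,
        direction="tutor->tutee",
        n_bouts_tutor=tutor.n_bouts,
        n_bouts_tutee=tutee.n_bouts,
        mc_samples=cfg.mc_samples,
        seed=cfg.seed,
        stderr_bits=kl.stderr_bits,
        low_bout_warning=low,
    )
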