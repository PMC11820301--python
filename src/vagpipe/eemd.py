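"""Ensemble empirical mode decomposition (EEMD).

Plain EMD suffers from mode mixing: a transient can pull oscillations of
very different timescales into the same IMF.  EEMD decomposes M white-noise
-perturbed copies of the signal,

    x_i(t) = x(t) + w_i(t),    i = 1..M,

and returns the per-mode ensemble means c_j(t) = (1/M) sum_i c_ij(t).  The
added noise populates the whole dyadic filter bank uniformly, so each
realisation's modes land in consistent frequency bands and the injected
noise cancels in the average (its residual shrinks like 1/sqrt(M)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .emd_core import IMFSet, NotSiftableError, SiftConfig, _emd_kernel
from .signal_model import InvalidInputError, Recording


@dataclass
class EEMDConfig:
    """Ensemble controls.

    ``noise_ratio`` is the white-noise standard deviation as a fraction of
    the signal's standard deviation (the "finite amplitude" of the added
    noise); ``ensembles`` is the number of perturbed realisations averaged.
    Realisation i draws its noise from an independent child stream of
    ``seed``, so results are reproducible and parallelisable.
    """

    ensembles: int = 100
    noise_ratio: float = 0.2
    seed: int = 0
    sift: SiftConfig = field(default_factory=SiftConfig)

    def __post_init__(self) -> None:
        if self.ensembles < 1:
            raise InvalidInputError("ensembles must be >= 1")
        if self.noise_ratio < 0:
            raise InvalidInputError("noise_ratio must be >= 0")


def eemd(recording: Recording | np.ndarray, cfg: EEMDConfig | None = None) -> IMFSet:
    """Noise-assisted decomposition with ensemble-averaged modes.

    Every realisation is decomposed with the shared :class:`SiftConfig`; the
    mode count is aligned to the configured budget by zero-padding missing
    high-order modes, so the ensemble mean of mode j is always over all M
    realisations.  With ``ensembles=1, noise_ratio=0`` this reduces exactly
    to plain EMD.
    """
    cfg = cfg or EEMDConfig()
    x = np.ascontiguousarray(
        recording.samples if isinstance(recording, Recording) else recording, dtype=float
    )
    if x.size < 3:
        raise InvalidInputError("signal too short to decompose")
    if np.ptp(x) == 0:
        raise NotSiftableError("constant signal cannot be decomposed")

    max_imfs = cfg.sift.resolve_max_imfs(x.size)
    sigma = cfg.noise_ratio * x.std()
    mean_imfs = np.zeros((max_imfs, x.size))
    mean_residual = np.zeros(x.size)

    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.ensembles)
    for i in range(cfg.ensembles):
        if sigma > 0:
            w = np.random.default_rng(children[i]).standard_normal(x.size) * sigma
            xi = x + w
        else:
            xi = x
        imfs, residual = _emd_kernel(
            xi,
            max_imfs,
            cfg.sift.max_sift_iters,
            cfg.sift.sd_threshold,
            cfg.sift.tol_mean,
            cfg.sift.envelope_extension,
        )
        mean_imfs[: imfs.shape[0]] += imfs
        # modes beyond this realisation's count contribute zeros; its
        # residual still belongs in the ensemble-mean residual
        mean_residual += residual
    mean_imfs /= cfg.ensembles
    mean_residual /= cfg.ensembles
    return IMFSet(
        imfs=[mean_imfs[j] for j in range(max_imfs)],
        residual=mean_residual,
        source_length=x.size,
    )
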