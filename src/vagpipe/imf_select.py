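"""Long-range-correlation-based IMF selection and reconstruction.

This is the filtering step the pipeline is built around: the recording is
decomposed with EEMD, every IMF (and the raw input, reported as "IN") gets
a DFA scaling exponent, and only modes in the long-range-correlated regime
0.5 < alpha < 1 are summed back into the reconstructed signal.  Modes that
scale like white noise, anticorrelated noise, or nonstationary trends are
dropped, so the reconstruction keeps the persistent, physiologically
structured part of the signal and discards broadband noise and drift.

The module also provides the cohort-level comparison of group median
exponents per component and per (chain, sensor) stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfa import DFAConfig, DFAResult, dfa_alpha
from .eemd import EEMDConfig, eemd
from .emd_core import IMFSet
from .signal_model import Group, InvalidInputError, Recording


class NoLRCError(ValueError):
    """No IMF fell in the LRC regime; carries the per-IMF alpha vector."""

    def __init__(self, per_imf_alpha: np.ndarray):
        self.per_imf_alpha = np.asarray(per_imf_alpha, dtype=float)
        super().__init__(
            "no IMF exhibits long-range correlation (0.5 < alpha < 1); "
            f"per-IMF alpha = {np.round(self.per_imf_alpha, 3).tolist()}"
        )


class IncompleteStratumError(ValueError):
    """A (chain, sensor) stratum is missing one of the two groups."""


LRC_LOW = 0.5
LRC_HIGH = 1.0


def lrc_mask(alphas: np.ndarray) -> np.ndarray:
    """Strict LRC selection: 0.5 < alpha < 1 per mode."""
    alphas = np.asarray(alphas, dtype=float)
    return (alphas > LRC_LOW) & (alphas < LRC_HIGH)


@dataclass
class FilterReport:
    """Outcome of filtering one recording.

    ``per_imf_alpha`` has one exponent per IMF; ``input_alpha`` is the raw
    signal's exponent (the "IN" row of cohort tables).  ``selected`` marks
    the LRC modes; ``reconstructed`` is their element-wise sum with the
    original sampling rate and metadata.
    """

    per_imf_alpha: np.ndarray
    input_alpha: float
    selected: np.ndarray
    reconstructed: Recording
    dfa_results: list[DFAResult]
    imfset: IMFSet | None = None

    def __post_init__(self) -> None:
        self.per_imf_alpha = np.asarray(self.per_imf_alpha, dtype=float)
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.size != self.per_imf_alpha.size:
            raise InvalidInputError("selected mask must match the number of IMFs")
        if not np.array_equal(self.selected, lrc_mask(self.per_imf_alpha)):
            raise InvalidInputError("selected mask inconsistent with per-IMF alphas")


def filter_recording(
    recording: Recording,
    eemd_cfg: EEMDConfig | None = None,
    dfa_cfg: DFAConfig | None = None,
    keep_imfset: bool = False,
) -> FilterReport:
    """EEMD-decompose, score each mode with DFA, keep the LRC modes.

    Raises :class:`NoLRCError` (carrying the alpha vector) when no mode
    qualifies; callers may fall back to the raw signal but never silently
    receive zeros.
    """
    eemd_cfg = eemd_cfg or EEMDConfig()
    dfa_cfg = dfa_cfg or DFAConfig()
    if recording.samples.size < 2 * dfa_cfg.n_max:
        raise InvalidInputError(
            f"recording too short for DFA: {recording.samples.size} < {2 * dfa_cfg.n_max}"
        )
    modes = eemd(recording, eemd_cfg)
    input_result = dfa_alpha(recording.samples, dfa_cfg)
    results: list[DFAResult] = []
    alphas = np.empty(modes.n_imfs)
    for j, imf in enumerate(modes.imfs):
        if np.ptp(imf) == 0:  # zero-padded trailing mode
            alphas[j] = np.nan
            results.append(
                DFAResult(
                    n_grid=dfa_cfg.grid,
                    F=np.full(dfa_cfg.grid.size, np.nan),
                    alpha=np.nan,
                    intercept=np.nan,
                    r_squared=np.nan,
                    regime=None,  # type: ignore[arg-type]
                )
            )
            continue
        res = dfa_alpha(imf, dfa_cfg)
        alphas[j] = res.alpha
        results.append(res)
    selected = lrc_mask(alphas)
    if not selected.any():
        raise NoLRCError(alphas)
    recon = np.sum([modes.imfs[j] for j in np.flatnonzero(selected)], axis=0)
    return FilterReport(
        per_imf_alpha=alphas,
        input_alpha=input_result.alpha,
        selected=selected,
        reconstructed=recording.with_samples(recon),
        dfa_results=[input_result] + results,
        imfset=modes if keep_imfset else None,
    )


def group_alpha_comparison(
    cohort: list[tuple[Recording, FilterReport]],
    strict_strata: bool = True,
) -> pd.DataFrame:
    """Percent difference of group median alpha per component and stratum.

    For every component (IN, IMF 1..K) and every (chain, sensor) cell the
    table holds 100 * |median_OA - median_HC| / |median_HC|.  The healthy
    controls are the reference denominator.  Every stratum must contain
    both groups unless ``strict_strata`` is disabled (missing cells then
    become NaN).
    """
    if not cohort:
        raise InvalidInputError("empty cohort")
    n_imfs = cohort[0][1].per_imf_alpha.size
    records = []
    for rec, report in cohort:
        if report.per_imf_alpha.size != n_imfs:
            raise InvalidInputError("all reports must share the same IMF count")
        row = {
            "group": rec.meta.group.value,
            "chain": rec.meta.chain.value,
            "sensor": rec.meta.sensor.value,
            "IN": report.input_alpha,
        }
        for j in range(n_imfs):
            row[f"IMF {j + 1}"] = report.per_imf_alpha[j]
        records.append(row)
    df = pd.DataFrame(records)
    components = ["IN"] + [f"IMF {j + 1}" for j in range(n_imfs)]
    cells = df.groupby(["chain", "sensor"])
    out_rows = {}
    for (chain, sensor), cell in cells:
        groups = set(cell["group"])
        if groups != {"HC", "OA"}:
            if strict_strata:
                raise IncompleteStratumError(
                    f"stratum ({chain}, {sensor}) is missing a group: has {sorted(groups)}"
                )
            out_rows[(chain, sensor)] = {c: np.nan for c in components}
            continue
        med = cell.groupby("group")[components].median()
        hc = med.loc["HC"]
        oa = med.loc["OA"]
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (oa - hc).abs() / hc.abs()
        out_rows[(chain, sensor)] = pct.to_dict()
    table = pd.DataFrame(out_rows).T
    table.index.names = ["chain", "sensor"]
    return table[components]
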