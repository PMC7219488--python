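"""Epoch-level morphology metrics and rater-decision bookkeeping.

Implements the cosine similarity index (each epoch against the average of ALL
epochs in its dataset), averaging of rater-accepted epochs, peak-negativity
(PN) labelling of an average MRCP, and matched-epoch indicator tables.

A "matched" epoch is one a single rater accepted at two different evaluation
sessions (intra-rater) or one all raters accepted within a single session
(inter-rater). Reject-reject pairs are deliberately NOT matched; matching is
defined through acceptance only. An optional agreement table counting both is
provided for completeness but plays no role in the headline analysis.

Tabular results are pandas DataFrames with documented columns; these map 1:1
onto the CSV interfaces of the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import EpochSet

__all__ = [
    "AverageMRCP",
    "PNLabel",
    "cosine_similarity",
    "similarity_table",
    "average_included",
    "label_pn",
    "matched_table",
    "agreement_table",
    "acceptance_mask",
]

logger = logging.getLogger(__name__)

#: Default PN search window in ms relative to the cue: covers the full stated
#: MRCP time course (negativity starting up to 2 s pre-cue, peak near movement
#: onset) without excluding any part of the displayed epoch a rater could pick.
DEFAULT_PN_WINDOW_MS = (-2000.0, 1500.0)


@dataclass
class AverageMRCP:
    """Average of the included epochs of one dataset (uV)."""

    dataset_id: str
    samples: np.ndarray
    n_included: int
    fs: float
    cue_index: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.n_included < 1:
            raise ValueError("an average MRCP needs at least one included epoch")

    @property
    def time_ms(self) -> np.ndarray:
        return (np.arange(self.samples.size) - self.cue_index) * 1000.0 / self.fs


@dataclass(frozen=True)
class PNLabel:
    """A peak-negativity label: latency in ms relative to cue, amplitude in uV."""

    dataset_id: str
    rater_id: str
    session: int
    pn_ms: float
    pn_amplitude: float


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """cos(u, v) = u.v / (||u|| ||v||), in [-1, 1].

    Raises ``ValueError`` on mismatched lengths or a zero-norm input.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.size != v.size:
        raise ValueError(f"length mismatch: {u.size} vs {v.size}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity is undefined for a zero-norm vector")
    return float(np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0))


def similarity_table(epochs: EpochSet) -> pd.DataFrame:
    """Cosine similarity of every epoch against the dataset's grand average.

    The reference vector is the average of ALL epochs in the dataset (not any
    accepted subset). Zero-norm epochs are flagged ``valid=False`` with
    ``cs=NaN`` and a warning is logged with the count; they are excluded from
    downstream association analyses, never silently dropped.

    Returns a DataFrame with columns dataset_id, epoch_index, cs, valid.
    """
    if epochs.n_epochs < 2:
        raise ValueError("similarity requires at least 2 epochs")
    grand = epochs.epochs.mean(axis=0)
    if np.linalg.norm(grand) == 0.0:
        raise ValueError("grand-average epoch has zero norm; similarity undefined")
    rows = []
    n_invalid = 0
    for i in range(epochs.n_epochs):
        v = epochs.epochs[i]
        if np.linalg.norm(v) == 0.0:
            rows.append((epochs.dataset_id, i, np.nan, False))
            n_invalid += 1
        else:
            rows.append((epochs.dataset_id, i, cosine_similarity(grand, v), True))
    if n_invalid:
        logger.warning(
            "dataset %s: %d zero-norm epoch(s) excluded from similarity",
            epochs.dataset_id,
            n_invalid,
        )
    return pd.DataFrame(rows, columns=["dataset_id", "epoch_index", "cs", "valid"])


def acceptance_mask(
    acceptances: pd.DataFrame, dataset_id: str, rater_id: str, session: int, n_epochs: int
) -> np.ndarray:
    """Boolean accept mask for one (dataset, rater, session) from a long table.

    ``acceptances`` columns: dataset_id, rater_id, session, epoch_index, accept.
    Raises ``ValueError`` naming any missing decision.
    """
    sub = acceptances[
        (acceptances["dataset_id"] == dataset_id)
        & (acceptances["rater_id"] == rater_id)
        & (acceptances["session"] == session)
    ]
    mask = np.zeros(n_epochs, dtype=bool)
    seen = np.zeros(n_epochs, dtype=bool)
    for _, row in sub.iterrows():
        idx = int(row["epoch_index"])
        mask[idx] = bool(row["accept"])
        seen[idx] = True
    if not seen.all():
        missing = np.flatnonzero(~seen)
        raise ValueError(
            f"missing accept decision for dataset={dataset_id}, rater={rater_id}, "
            f"session={session}, epoch(s) {missing.tolist()}"
        )
    return mask


def average_included(epochs: EpochSet, accept) -> AverageMRCP:
    """Average the accepted epochs of a dataset (element-wise mean, uV).

    ``accept`` is a boolean mask over epochs, or a long acceptance DataFrame
    restricted to exactly one (rater, session) for this dataset.
    Raises ``ValueError`` if no epoch is accepted.
    """
    if isinstance(accept, pd.DataFrame):
        key = accept[["rater_id", "session"]].drop_duplicates()
        if len(key) != 1:
            raise ValueError(
                "acceptance table must contain exactly one (rater, session)"
            )
        rater, session = key.iloc[0]
        accept = acceptance_mask(
            accept, epochs.dataset_id, rater, int(session), epochs.n_epochs
        )
    accept = np.asarray(accept, dtype=bool)
    if accept.shape != (epochs.n_epochs,):
        raise ValueError(
            f"accept mask length {accept.shape} does not match {epochs.n_epochs} epochs"
        )
    n_inc = int(accept.sum())
    if n_inc == 0:
        raise ValueError(f"no epochs included for dataset {epochs.dataset_id}")
    return AverageMRCP(
        dataset_id=epochs.dataset_id,
        samples=epochs.epochs[accept].mean(axis=0),
        n_included=n_inc,
        fs=epochs.fs,
        cue_index=epochs.cue_index,
    )


def label_pn(
    avg: AverageMRCP,
    window_ms: tuple[float, float] = DEFAULT_PN_WINDOW_MS,
    rater_id: str = "auto",
    session: int = 0,
) -> PNLabel:
    """Label the peak negativity: the most negative sample inside the window.

    Latency is reported in ms relative to the cue. Ties break to the earliest
    sample. A constant signal in the window has no defined PN and raises.
    """
    t = avg.time_ms
    lo, hi = window_ms
    if lo >= hi:
        raise ValueError("PN window must satisfy lo < hi")
    in_win = (t >= lo) & (t <= hi)
    if not in_win.any():
        raise ValueError("PN search window does not intersect the epoch")
    seg = avg.samples[in_win]
    if np.ptp(seg) == 0.0:
        raise ValueError(
            f"dataset {avg.dataset_id}: signal constant in PN window, no defined PN"
        )
    rel = int(np.argmin(seg))  # argmin returns the first (earliest) minimum
    idx = np.flatnonzero(in_win)[rel]
    return PNLabel(
        dataset_id=avg.dataset_id,
        rater_id=rater_id,
        session=session,
        pn_ms=float(t[idx]),
        pn_amplitude=float(avg.samples[idx]),
    )


def _decision_lookup(acceptances: pd.DataFrame):
    """(dataset, rater, session, epoch) -> accept dict with duplicate check."""
    lut: dict[tuple, bool] = {}
    for row in acceptances.itertuples(index=False):
        key = (row.dataset_id, row.rater_id, int(row.session), int(row.epoch_index))
        lut[key] = bool(row.accept)
    return lut


def matched_table(acceptances: pd.DataFrame, mode: tuple) -> pd.DataFrame:
    """Matched-epoch indicators from a long acceptance table.

    ``mode`` is ``("intra", rater_id, session_a, session_b)`` — matched iff
    that rater accepted the epoch at BOTH sessions — or ``("inter", session)``
    — matched iff ALL raters in the table accepted the epoch at that session.

    Returns a DataFrame with columns dataset_id, epoch_index, comparison,
    matched. Raises ``ValueError`` identifying any missing decision.
    """
    lut = _decision_lookup(acceptances)
    datasets = sorted(acceptances["dataset_id"].unique())
    epochs_per = {
        d: sorted(acceptances.loc[acceptances["dataset_id"] == d, "epoch_index"].unique())
        for d in datasets
    }
    rows = []
    if mode[0] == "intra":
        _, rater, s1, s2 = mode
        comparison = f"intra({rater},{s1},{s2})"
        for d in datasets:
            for e in epochs_per[d]:
                vals = []
                for s in (int(s1), int(s2)):
                    key = (d, rater, s, int(e))
                    if key not in lut:
                        raise ValueError(
                            f"missing decision: dataset={d}, rater={rater}, "
                            f"session={s}, epoch={e}"
                        )
                    vals.append(lut[key])
                rows.append((d, int(e), comparison, all(vals)))
    elif mode[0] == "inter":
        _, session = mode
        session = int(session)
        raters = sorted(acceptances["rater_id"].unique())
        comparison = f"inter({session})"
        for d in datasets:
            for e in epochs_per[d]:
                vals = []
                for r in raters:
                    key = (d, r, session, int(e))
                    if key not in lut:
                        raise ValueError(
                            f"missing decision: dataset={d}, rater={r}, "
                            f"session={session}, epoch={e}"
                        )
                    vals.append(lut[key])
                rows.append((d, int(e), comparison, all(vals)))
    else:
        raise ValueError(f"unknown matched mode {mode!r}")
    return pd.DataFrame(rows, columns=["dataset_id", "epoch_index", "comparison", "matched"])


def agreement_table(acceptances: pd.DataFrame, mode: tuple) -> pd.DataFrame:
    """Like :func:`matched_table` but counting unanimous decisions of either
    sign (accept-accept OR reject-reject). Not used in the headline analysis.
    """
    lut = _decision_lookup(acceptances)
    matched = matched_table(acceptances, mode)
    rows = []
    for row in matched.itertuples(index=False):
        if mode[0] == "intra":
            _, rater, s1, s2 = mode
            vals = [lut[(row.dataset_id, rater, int(s), row.epoch_index)] for s in (s1, s2)]
        else:
            raters = sorted(acceptances["rater_id"].unique())
            vals = [
                lut[(row.dataset_id, r, int(mode[1]), row.epoch_index)] for r in raters
            ]
        rows.append(
            (row.dataset_id, row.epoch_index, row.comparison, all(vals) or not any(vals))
        )
    return pd.DataFrame(rows, columns=["dataset_id", "epoch_index", "comparison", "agree"])
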