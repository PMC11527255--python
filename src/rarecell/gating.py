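"""Phenotype gating: WBC / CTC / CTC-IGC calls and sample enumeration.

A circulating tumor cell (CTC) is DAPI+/EPI+/CD45−; a white blood cell
(WBC) is DAPI+/CD45+ (the exclusion marker wins regardless of EPI).  A
CTC with increased genomic content (CTC-IGC) is a CTC whose nuclear
equivalent diameter is at least ``igc_ratio`` (default 2.0) times the
average diameter of the sample's CTC population.  Because giant cells
inflate the very average they are compared against, the default rule
iterates: flagged cells are removed from the reference mean and the flags
recomputed until a fixed point — the flagged set only grows, so the
iteration terminates.  Channel positivity thresholds default to
background median + k·sd per channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import CellRecord

__all__ = [
    "GateConfig",
    "SampleEnumeration",
    "immunophenotype",
    "classify_igc",
    "marker_positive",
    "enumerate_sample",
    "summarize_cohort",
]


@dataclass
class GateConfig:
    """Positivity thresholds and the CTC-IGC size rule.

    A channel is positive when the relevant mean intensity exceeds
    ``background + k_sigma * background_sd``, unless an absolute cutoff
    for that channel is supplied in ``absolute_cutoffs``.  DAPI is gated
    on the nucleus mean; membrane markers (EPI, CD45, VAR) on the cell
    mean.  ``igc_reference`` selects how the reference average is formed:
    ``"iterated"`` (default) excludes already-flagged giants and repeats
    to a fixed point; ``"single_pass"`` uses the plain one-shot mean.
    ``igc_statistic`` chooses mean or median for the reference.
    """

    k_sigma: float = 3.0
    absolute_cutoffs: dict[str, float] = field(default_factory=dict)
    igc_ratio: float = 2.0
    igc_reference: str = "iterated"
    igc_statistic: str = "mean"

    def __post_init__(self) -> None:
        if self.igc_ratio <= 1:
            raise ValueError("igc_ratio must be > 1")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be > 0")
        if self.igc_reference not in ("iterated", "single_pass"):
            raise ValueError("igc_reference must be 'iterated' or 'single_pass'")
        if self.igc_statistic not in ("mean", "median"):
            raise ValueError("igc_statistic must be 'mean' or 'median'")


@dataclass
class SampleEnumeration:
    """Per-sample cell counts and derived fractions.

    ``igc_positive`` means at least one CTC-IGC was detected.  The
    marker cross-tabulation records VAR positivity against EPI status so
    that EPI−/marker+ cells are reported as their own category, never
    silently merged into the CTC count.
    """

    sample_id: str
    n_wbc: int
    n_ctc: int
    n_ctc_igc: int
    n_other: int
    n_epi_pos_marker_pos: int
    n_epi_pos_marker_neg: int
    n_epi_neg_marker_pos: int
    igc_positive: bool
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.n_wbc + self.n_ctc + self.n_ctc_igc + self.n_other


def _threshold(channel: str, gates: GateConfig, background: dict[str, tuple[float, float]]) -> float:
    if channel in gates.absolute_cutoffs:
        return gates.absolute_cutoffs[channel]
    if channel not in background:
        raise ValueError(f"no background estimate for channel {channel!r}")
    med, sd = background[channel]
    return med + gates.k_sigma * sd


def _stat(rec: CellRecord, key: str) -> float:
    if key not in rec.channel_stats:
        raise ValueError(f"record {rec.cell_id} missing channel statistic {key!r}")
    return rec.channel_stats[key]


def immunophenotype(
    records: list[CellRecord],
    gates: GateConfig,
    background: dict[str, tuple[float, float]],
) -> list[str]:
    """Label each cell WBC, CTC_candidate, or other.

    CD45 positivity takes precedence (any CD45+ cell is a WBC); a
    CTC_candidate is DAPI+/EPI+/CD45−; everything else — including
    DAPI+/EPI−/CD45− cells — is 'other'.
    """
    thr_dapi = _threshold("DAPI", gates, background)
    thr_epi = _threshold("EPI", gates, background)
    thr_cd45 = _threshold("CD45", gates, background)
    labels = []
    for rec in records:
        dapi = _stat(rec, "DAPI_nucleus_mean")
        epi = _stat(rec, "EPI_cell_mean")
        cd45 = _stat(rec, "CD45_cell_mean")
        dapi_pos = np.isfinite(dapi) and dapi > thr_dapi
        if cd45 > thr_cd45:
            labels.append("WBC")
        elif dapi_pos and epi > thr_epi:
            labels.append("CTC_candidate")
        else:
            labels.append("other")
    return labels


def classify_igc(
    diameters: np.ndarray | list[float], gates: GateConfig | None = None
) -> tuple[np.ndarray, float]:
    """Flag CTC-IGC among CTC candidates by nuclear diameter.

    ``diameters`` are nuclear equivalent diameters (µm) of the sample's
    CTC candidates.  A cell is flagged when its diameter is at least
    ``igc_ratio`` times the reference average.  Under the default
    iterated rule each cell is compared against the average of the
    *other*, unflagged cells (so a giant never dilutes the reference it
    is judged by), and flags are recomputed until the flagged set stops
    growing — it is monotone non-decreasing, so the iteration terminates.
    The rule compares ratios only and is therefore scale invariant.
    Returns ``(flags, reference)`` where the reference is the final
    average over unflagged cells.  An empty input yields an empty flag
    vector (a CTC-negative sample is not an error).
    """
    gates = gates or GateConfig()
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        return np.zeros(0, dtype=bool), float("nan")
    if (d <= 0).any() or not np.isfinite(d).all():
        raise ValueError("diameters must be positive and finite")
    stat = np.mean if gates.igc_statistic == "mean" else np.median

    if gates.igc_reference == "single_pass":
        ref = float(stat(d))
        return d >= gates.igc_ratio * ref, ref

    flags = np.zeros(d.size, dtype=bool)
    while True:
        idx = np.flatnonzero(~flags)
        if idx.size <= 1:
            break  # a lone candidate has no reference population
        new = flags.copy()
        for i in idx:
            others = d[idx[idx != i]]
            if d[i] >= gates.igc_ratio * float(stat(others)):
                new[i] = True
        if (new == flags).all():
            break
        flags = new  # monotone growth only
    unflagged = d[~flags]
    ref = float(stat(unflagged)) if unflagged.size else float("nan")
    return flags, ref


def marker_positive(
    records: list[CellRecord],
    gates: GateConfig,
    background: dict[str, tuple[float, float]],
    channel: str = "VAR",
) -> np.ndarray:
    """Boolean per cell: mean intensity in ``channel`` above background gate."""
    thr = _threshold(channel, gates, background)
    return np.array([_stat(r, f"{channel}_cell_mean") > thr for r in records])


def enumerate_sample(
    labels: list[str],
    igc_flags: np.ndarray,
    marker_flags: np.ndarray,
    sample_id: str,
) -> SampleEnumeration:
    """Tally one sample's phenotype calls into a SampleEnumeration.

    ``igc_flags`` aligns with the CTC_candidate subset of ``labels`` (in
    order); ``marker_flags`` aligns with all records.  A sample is
    IGC-positive iff at least one CTC-IGC was found.
    """
    labels = list(labels)
    igc_flags = np.asarray(igc_flags, dtype=bool)
    marker_flags = np.asarray(marker_flags, dtype=bool)
    ctc_idx = [i for i, lab in enumerate(labels) if lab == "CTC_candidate"]
    if len(ctc_idx) != len(igc_flags):
        raise ValueError("igc_flags must align with the CTC_candidate subset")
    if len(labels) != len(marker_flags):
        raise ValueError("marker_flags must align with all records")

    n_wbc = labels.count("WBC")
    n_igc = int(igc_flags.sum())
    n_ctc = len(ctc_idx) - n_igc
    n_other = labels.count("other")

    epi_pos = np.zeros(len(labels), dtype=bool)
    epi_pos[ctc_idx] = True
    n_pp = int((epi_pos & marker_flags).sum())
    n_pn = int((epi_pos & ~marker_flags).sum())
    # EPI-negative, non-WBC cells carrying the marker: reported separately
    non_wbc = np.array([lab != "WBC" for lab in labels], dtype=bool)
    n_np = int((~epi_pos & non_wbc & marker_flags).sum())

    total = n_wbc + n_ctc + n_igc + n_other
    fractions = {}
    if total:
        fractions = {
            "wbc": n_wbc / total,
            "ctc": n_ctc / total,
            "ctc_igc": n_igc / total,
            "other": n_other / total,
        }
    n_epi = n_ctc + n_igc
    if n_epi:
        fractions["epi_marker_pos"] = n_pp / n_epi
    return SampleEnumeration(
        sample_id=sample_id,
        n_wbc=n_wbc,
        n_ctc=n_ctc,
        n_ctc_igc=n_igc,
        n_other=n_other,
        n_epi_pos_marker_pos=n_pp,
        n_epi_pos_marker_neg=n_pn,
        n_epi_neg_marker_pos=n_np,
        igc_positive=n_igc >= 1,
        fractions=fractions,
    )


def summarize_cohort(enumerations: list[SampleEnumeration]) -> pd.DataFrame:
    """Cohort-level summary: per-sample counts plus IGC positivity percent.

    Returns a one-row-per-sample table; the IGC positivity rate of the
    cohort (percent of samples with at least one CTC-IGC, 1 decimal
    place) is stored in ``df.attrs['igc_positivity_pct']``.
    """
    rows = [
        {
            "sample_id": e.sample_id,
            "n_wbc": e.n_wbc,
            "n_ctc": e.n_ctc,
            "n_ctc_igc": e.n_ctc_igc,
            "n_other": e.n_other,
            "igc_positive": e.igc_positive,
        }
        for e in enumerations
    ]
    df = pd.DataFrame(rows)
    if len(df):
        pct = 100.0 * df["igc_positive"].sum() / len(df)
        df.attrs["igc_positivity_pct"] = round(pct, 1)
    return df
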