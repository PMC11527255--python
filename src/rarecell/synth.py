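"""Synthetic data generators for every pipeline input, with ground truth.

Emulates the statistical structure of the study's data sources so the
whole analysis is testable without patient material or sequencing runs:

* rendered four-channel immunofluorescence slides (DAPI / EPI / CD45 /
  VAR) carrying WBCs, CTCs and CTC-IGCs as non-overlapping disks with a
  truth table of class labels, centroids and nuclear diameters;
* per-cell genomic bin counts for clonal copy-number profiles with an
  optional whole-genome-doubling multiplier, negative-binomial noise and
  a smooth quadratic GC bias;
* single-cell RNA count matrices for two cell lines under control and
  treated conditions, with log-normal baselines, NB noise, logistic
  dropout, batch effects, and a planted "survivor" signature up-regulated
  in the treated cells of both lines;
* exponential survival cohorts with a group-specific hazard ratio and
  independent censoring.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk as draw_disk

from .cnv import BinCounts
from .expr import CountMatrix
from .imaging import DEFAULT_CHANNELS, SlideImage

__all__ = [
    "CLASSES",
    "SlideSpec",
    "GroundTruthCell",
    "ClonalCNSpec",
    "ExprSimSpec",
    "CohortSpec",
    "generate_slide",
    "generate_bin_counts",
    "generate_expression",
    "generate_cohort",
    "default_genome_bins",
    "random_clone_cn",
    "add_spots",
]

CLASSES = ("WBC", "CTC", "CTC_IGC")


def _default_nucleus_diameters() -> dict[str, tuple[float, float]]:
    return {"WBC": (9.0, 0.8), "CTC": (12.0, 1.2), "CTC_IGC": (32.0, 2.5)}


def _default_cell_diameters() -> dict[str, tuple[float, float]]:
    return {"WBC": (12.0, 1.0), "CTC": (18.0, 1.5), "CTC_IGC": (38.0, 3.0)}


def _default_intensities() -> dict[str, dict[str, float]]:
    # DAPI renders on the nucleus; EPI/CD45/VAR on the cytoplasm.
    return {
        "WBC": {"DAPI": 3000.0, "EPI": 0.0, "CD45": 2500.0, "VAR": 2000.0},
        "CTC": {"DAPI": 3000.0, "EPI": 2500.0, "CD45": 0.0, "VAR": 2000.0},
        "CTC_IGC": {"DAPI": 3000.0, "EPI": 2500.0, "CD45": 0.0, "VAR": 2000.0},
    }


def _default_marker_fractions() -> dict[str, float]:
    return {"WBC": 0.0, "CTC": 0.3, "CTC_IGC": 0.5}


@dataclass
class SlideSpec:
    """Parameters of a rendered immunofluorescence slide.

    Cells are hard disks (cytoplasm disk with a concentric interior
    nucleus disk) with a light Gaussian edge blur; diameters are sampled
    per class from normal distributions in micrometers.  The default
    pixel size of 0.65 µm/px corresponds to a typical 10x slide scanner.
    The VAR channel lights up only for cells drawn marker-positive.
    Bit depth and background statistics are assumptions, not measured
    scanner properties; both are configurable here.
    """

    width_px: int = 1200
    height_px: int = 1200
    pixel_size_um: float = 0.65
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    n_wbc: int = 50
    n_ctc: int = 20
    n_igc: int = 2
    nucleus_diameter_um: dict[str, tuple[float, float]] = field(
        default_factory=_default_nucleus_diameters
    )
    cell_diameter_um: dict[str, tuple[float, float]] = field(
        default_factory=_default_cell_diameters
    )
    intensity: dict[str, dict[str, float]] = field(default_factory=_default_intensities)
    background_level: float = 200.0
    noise_sd: float = 20.0
    edge_blur_sigma_px: float = 0.0  # hard disks by default: area -> diameter exact
    marker_positive_fraction: dict[str, float] = field(
        default_factory=_default_marker_fractions
    )
    max_placement_attempts: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wbc, self.n_ctc, self.n_igc) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for cls in CLASSES:
            if self.nucleus_diameter_um[cls][0] <= 0 or self.cell_diameter_um[cls][0] <= 0:
                raise ValueError("diameter means must be positive")
        if (
            self.nucleus_diameter_um["CTC_IGC"][0]
            < 2.0 * self.nucleus_diameter_um["CTC"][0]
        ):
            raise ValueError(
                "CTC_IGC nuclear diameter mean must be at least twice the CTC mean"
            )


@dataclass(frozen=True)
class GroundTruthCell:
    """Truth-table row for one rendered cell."""

    cell_id: int
    class_label: str
    centroid: tuple[float, float]  # (row, col) pixels
    nucleus_diameter_um: float
    marker_positive: bool


def _sample_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0:
            return float(v)
    return mean


def generate_slide(spec: SlideSpec) -> tuple[SlideImage, list[GroundTruthCell]]:
    """Render a multi-channel slide and return it with its truth table.

    Cells are placed by rejection sampling so cytoplasm disks never
    overlap (the feature extractor has no declumping stage); a spec too
    dense to place within ``max_placement_attempts`` per cell raises a
    ``RuntimeError``.  Same seed, same spec: byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    channels = {ch: np.full((h, w), spec.background_level) for ch in spec.channel_names}

    plan = (
        [("WBC", i) for i in range(spec.n_wbc)]
        + [("CTC", i) for i in range(spec.n_ctc)]
        + [("CTC_IGC", i) for i in range(spec.n_igc)]
    )
    placed: list[tuple[float, float, float]] = []  # (row, col, cytoplasm radius px)
    truth: list[GroundTruthCell] = []
    for cell_id, (cls, _) in enumerate(plan, start=1):
        nuc_d = _sample_positive(rng, *spec.nucleus_diameter_um[cls])
        cyt_d = max(_sample_positive(rng, *spec.cell_diameter_um[cls]), nuc_d + 1.0)
        r_cyt = cyt_d / spec.pixel_size_um / 2.0
        r_nuc = nuc_d / spec.pixel_size_um / 2.0
        margin = r_cyt + 3.0
        if 2 * margin >= min(h, w):
            raise RuntimeError(f"cell of class {cls} does not fit in the image")
        ok = False
        for _ in range(spec.max_placement_attempts):
            row = rng.uniform(margin, h - margin)
            col = rng.uniform(margin, w - margin)
            if all(
                np.hypot(row - r0, col - c0) > r_cyt + rr + 4.0
                for r0, c0, rr in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place cell {cell_id} ({cls}) without overlap after "
                f"{spec.max_placement_attempts} attempts; reduce density"
            )
        placed.append((row, col, r_cyt))

        marker = bool(rng.random() < spec.marker_positive_fraction.get(cls, 0.0))
        inten = spec.intensity[cls]
        for ch in spec.channel_names:
            amp = inten.get(ch, 0.0)
            if ch == "VAR" and not marker:
                amp = 0.0
            if amp <= 0:
                continue
            radius = r_nuc if ch == "DAPI" else r_cyt
            rr_px, cc_px = draw_disk((row, col), radius, shape=(h, w))
            channels[ch][rr_px, cc_px] += amp
        truth.append(
            GroundTruthCell(
                cell_id=cell_id,
                class_label=cls,
                centroid=(row, col),
                nucleus_diameter_um=nuc_d,
                marker_positive=marker,
            )
        )

    for ch in spec.channel_names:
        img = channels[ch]
        if spec.edge_blur_sigma_px > 0:
            img = gaussian_filter(img, sigma=spec.edge_blur_sigma_px)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[ch] = np.clip(img, 0.0, 65535.0)

    return SlideImage(channels=channels, pixel_size_um=spec.pixel_size_um), truth


def add_spots(
    image: np.ndarray,
    positions: list[tuple[float, float]],
    amplitude: float = 2000.0,
    sigma_px: float = 1.2,
) -> np.ndarray:
    """Add Gaussian puncta (FISH probe signals) to an image, returning a copy."""
    out = np.asarray(image, dtype=float).copy()
    h, w = out.shape
    yy, xx = np.mgrid[0:h, 0:w]
    for r, c in positions:
        out += amplitude * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma_px**2))
    return out


def default_genome_bins(
    n_bins: int = 2000,
    n_chroms: int = 10,
    bin_size: int = 1_000_000,
    seed: int = 0,
) -> pd.DataFrame:
    """A simple genome bin schema with smoothly varying GC fraction."""
    rng = np.random.default_rng(seed)
    per = n_bins // n_chroms
    rows = []
    for c in range(n_chroms):
        n = per + (n_bins - per * n_chroms if c == n_chroms - 1 else 0)
        gc = 0.45 + 0.08 * np.sin(np.linspace(0, 3 * np.pi, n) + c)
        gc = np.clip(gc + rng.normal(0, 0.02, size=n), 0.3, 0.65)
        for i in range(n):
            rows.append(
                {
                    "chrom": f"chr{c + 1}",
                    "start": i * bin_size,
                    "end": (i + 1) * bin_size,
                    "gc": float(gc[i]),
                }
            )
    return pd.DataFrame(rows)


def random_clone_cn(
    bins: pd.DataFrame,
    seed: int = 0,
    levels: tuple[int, ...] = (1, 2, 3, 4),
    segments_per_chrom: int = 2,
) -> np.ndarray:
    """Draw an aneuploid clonal copy-number profile over the bin schema.

    Each chromosome is split into ``segments_per_chrom`` equal blocks
    (arms, by default) and each block gets an integer copy number drawn
    uniformly from ``levels`` — emulating the broad arm-level gains and
    losses of heavily rearranged tumor genomes, whose between-bin
    variance is what makes ratio profiles identifiable.
    """
    rng = np.random.default_rng(seed)
    cn = np.empty(len(bins))
    for _, grp in bins.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        blocks = np.array_split(idx, segments_per_chrom)
        for b in blocks:
            cn[b] = rng.choice(levels)
    return cn


@dataclass
class ClonalCNSpec:
    """A clonal integer copy-number profile plus sequencing-noise model.

    Per-bin expected counts are proportional to
    ``copy_number x wgd_multiplier x gc_bias(gc)`` where the GC bias is
    quadratic in GC fraction (normalized to mean 1 so a flat profile at
    CN 2 and ``wgd_multiplier`` 1 averages ``mean_reads_per_bin``).
    Counts are negative binomial with variance mu + dispersion * mu^2.
    """

    bins: pd.DataFrame
    copy_number: np.ndarray
    wgd_multiplier: int = 1
    mean_reads_per_bin: float = 500.0
    gc_coeffs: tuple[float, float, float] = (1.0, 0.0, 0.0)
    dispersion: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.bins) == 0:
            raise ValueError("empty bin list")
        self.copy_number = np.asarray(self.copy_number, dtype=float)
        if len(self.copy_number) != len(self.bins):
            raise ValueError("copy_number length must match bins")
        if (self.copy_number < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if self.wgd_multiplier not in (1, 2, 4):
            raise ValueError("wgd_multiplier must be 1, 2 or 4")
        gc = self.bins["gc"].to_numpy(dtype=float)
        if ((gc < 0) | (gc > 1)).any():
            raise ValueError("gc_fraction must lie in [0, 1]")


def generate_bin_counts(spec: ClonalCNSpec, n_cells: int = 1) -> BinCounts:
    """Draw per-cell bin counts for one clone.

    Expected count per bin: ``mean_reads_per_bin x (CN/2) x wgd x
    gc_bias_norm(gc)``, so doubling the WGD multiplier doubles every
    expectation (total read depth scales with genome content).
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.bins["gc"].to_numpy(dtype=float)
    c0, c1, c2 = spec.gc_coeffs
    bias = np.maximum(c0 + c1 * gc + c2 * gc**2, 0.05)
    bias = bias / bias.mean()
    mu = spec.mean_reads_per_bin * (spec.copy_number / 2.0) * spec.wgd_multiplier * bias
    counts = np.empty((n_cells, len(mu)), dtype=int)
    for i in range(n_cells):
        if spec.dispersion <= 1e-8:
            counts[i] = rng.poisson(mu)
        else:
            r = 1.0 / spec.dispersion
            p = r / (r + np.maximum(mu, 1e-12))
            counts[i] = rng.negative_binomial(r, p)
    return BinCounts(bins=spec.bins, counts=counts)


@dataclass
class ExprSimSpec:
    """Single-cell RNA simulation: two lines, control + treated conditions.

    Baseline per-gene means are log-normal; counts are negative binomial
    around line/condition/batch-adjusted means; dropout zeroes a detected
    count with probability ``1 - sigmoid(a + b log mu)``; the survivor
    signature (gene index -> log2 LFC) is applied in every *treated*
    (non-control) condition of *both* lines, while ``line_specific``
    signatures apply only to the treated conditions of their own line.
    """

    n_genes: int = 2000
    lines: tuple[str, ...] = ("MDA", "PC3")
    conditions: tuple[str, ...] = ("control", "cis", "doc")
    control_condition: str = "control"
    cells_per_condition: int = 60
    baseline_meanlog: float = 3.0  # deep full-length (Smart-seq2-like) libraries
    baseline_sdlog: float = 1.2
    dispersion: float = 0.3
    cell_size_sdlog: float = 0.3  # technical per-cell depth variability
    dropout_intercept: float = 0.0
    dropout_slope: float = 1.5
    apply_dropout: bool = True
    n_batches: int = 2
    batch_effect_sd: float = 0.2  # log2 scale
    survivor_signature: dict[int, float] = field(default_factory=dict)
    line_specific: dict[str, dict[int, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.cells_per_condition < 1:
            raise ValueError("n_genes and cells_per_condition must be >= 1")
        for idx in self.survivor_signature:
            if not 0 <= idx < self.n_genes:
                raise ValueError(f"signature gene index {idx} out of range")
        for line, sig in self.line_specific.items():
            if line not in self.lines:
                raise ValueError(f"unknown line {line!r} in line_specific")
            for idx in sig:
                if not 0 <= idx < self.n_genes:
                    raise ValueError(f"line-specific gene index {idx} out of range")
        if self.control_condition not in self.conditions:
            raise ValueError("control_condition must be among conditions")


def generate_expression(spec: ExprSimSpec) -> CountMatrix:
    """Simulate a genes x cells count matrix with metadata.

    Cell metadata columns: ``cell_id``, ``line``, ``condition``,
    ``batch`` (batches assigned round-robin within each line/condition so
    batch is never confounded with the contrasts).
    """
    rng = np.random.default_rng(spec.seed)
    baseline = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_genes)
    batch_fx = 2.0 ** rng.normal(
        0.0, spec.batch_effect_sd, size=(spec.n_batches, spec.n_genes)
    )

    sig = np.zeros(spec.n_genes)
    for idx, lfc in spec.survivor_signature.items():
        sig[idx] = lfc

    cols, metas = [], []
    cell_i = 0
    for line in spec.lines:
        line_sig = np.zeros(spec.n_genes)
        for idx, lfc in spec.line_specific.get(line, {}).items():
            line_sig[idx] = lfc
        for cond in spec.conditions:
            treated = cond != spec.control_condition
            shift = 2.0 ** (sig + line_sig) if treated else 1.0
            for j in range(spec.cells_per_condition):
                batch = j % spec.n_batches
                cell_size = rng.lognormal(0.0, spec.cell_size_sdlog)
                mu = baseline * shift * batch_fx[batch] * cell_size
                if spec.dispersion <= 1e-8:
                    y = rng.poisson(mu)
                else:
                    r = 1.0 / spec.dispersion
                    p = r / (r + np.maximum(mu, 1e-12))
                    y = rng.negative_binomial(r, p)
                if spec.apply_dropout:
                    logit = spec.dropout_intercept + spec.dropout_slope * np.log(
                        np.maximum(mu, 1e-12)
                    )
                    p_det = 1.0 / (1.0 + np.exp(-logit))
                    y = np.where(rng.random(spec.n_genes) < p_det, y, 0)
                cols.append(y)
                metas.append(
                    {
                        "cell_id": f"{line}_{cond}_{j}",
                        "line": line,
                        "condition": cond,
                        "batch": f"b{batch}",
                    }
                )
                cell_i += 1

    counts = np.column_stack(cols)
    gene_ids = [f"gene{i}" for i in range(spec.n_genes)]
    return CountMatrix(counts=counts, gene_ids=gene_ids, meta=pd.DataFrame(metas))


@dataclass
class CohortSpec:
    """Exponential survival cohort with a two-group hazard ratio.

    Event times are exponential with hazard ``baseline_hazard`` (events
    per month) for the negative group and ``baseline_hazard x
    hazard_ratio`` for the positive group; censoring is an independent
    exponential chosen so that roughly ``censoring_rate`` of negative-
    group subjects are censored.
    """

    n_subjects: int = 100
    positivity_probability: float = 0.5
    baseline_hazard: float = 0.05
    hazard_ratio: float = 2.0
    censoring_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a cohort table: columns id, group, time, event."""
    rng = np.random.default_rng(spec.seed)
    positive = rng.random(spec.n_subjects) < spec.positivity_probability
    hazard = np.where(
        positive, spec.baseline_hazard * spec.hazard_ratio, spec.baseline_hazard
    )
    t_event = rng.exponential(1.0 / hazard)
    if spec.censoring_rate > 0:
        mu = spec.baseline_hazard * spec.censoring_rate / (1.0 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / mu, size=spec.n_subjects)
    else:
        t_cens = np.full(spec.n_subjects, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "id": [f"s{i}" for i in range(spec.n_subjects)],
            "group": np.where(positive, "positive", "negative"),
            "time": np.maximum(time, 1e-9),
            "event": event,
        }
    )
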