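"""Chromosome-conformation analysis: synthetic contact matrices, the
event-vs-contact moving-average correlation, and ROI bait profiles.

Contact matrices here play the role of normalized Hi-C maps binned at 10 kb.
The synthetic generator produces the canonical polymer distance-decay
pattern, ``M[i,j] ~ d(i,j)^alpha`` with ``alpha < 0``, where genomic distance
``d`` is ``|i-j|`` for a linear chromosome and the arc distance
``min(|i-j|, n-|i-j|)`` for a circular one — circularization therefore
brings the two chromosome ends into contact, the feature that distinguishes
a ring chromosome's map.

The correlation analysis asks whether recombination happens preferentially
between loci that touch: bin pairs are annotated with their event count and
contact strength, pairs with zero events or zero contacts are dropped,
the remainder is sorted by contact strength and smoothed with a moving
average (window 10, shift 3), and Pearson's r with a least-squares line is
computed on the averaged points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ContactMatrix:
    """Symmetric, normalized, binned intra-chromosomal contact map."""

    matrix: np.ndarray
    bin_size: int = 10_000
    topology: str = "linear"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(m, m.T, rtol=1e-8, atol=1e-10):
            raise ValueError("contact matrix must be symmetric")
        if not np.isfinite(m).all() or (m < 0).any():
            raise ValueError("contact matrix entries must be finite and "
                             "non-negative")
        self.matrix = m

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class ROISpec:
    """Two disjoint terminal windows (bin-unit half-open intervals), the
    30 kb subtelomeric baits of the conformation analysis."""

    window1: tuple[int, int]
    window2: tuple[int, int]

    def validate(self, n_bins: int) -> None:
        for a, b in (self.window1, self.window2):
            if not 0 <= a < b <= n_bins:
                raise ValueError(f"ROI window [{a},{b}) outside matrix")
        a1, b1 = self.window1
        a2, b2 = self.window2
        if a1 < b2 and a2 < b1:
            raise ValueError("ROI windows overlap")

    def bins(self) -> set[int]:
        return set(range(*self.window1)) | set(range(*self.window2))


def default_roi(n_bins: int, roi_bp: int = 30_000,
                bin_size: int = 10_000) -> ROISpec:
    w = max(1, roi_bp // bin_size)
    return ROISpec((0, w), (n_bins - w, n_bins))


# ---------------------------------------------------------------------------
# synthetic matrices
# ---------------------------------------------------------------------------

def bin_distance(n_bins: int, topology: str) -> np.ndarray:
    i = np.arange(n_bins)
    d = np.abs(i[:, None] - i[None, :])
    if topology == "circular":
        d = np.minimum(d, n_bins - d)
    return d


def synth_contact_matrix(n_bins: int, topology: str = "linear",
                         decay_exponent: float = -1.0,
                         noise_sd: float = 0.0, seed: int = 0,
                         bin_size: int = 10_000,
                         total: float = 1e6) -> ContactMatrix:
    """Distance-decay contact matrix with multiplicative lognormal noise,
    symmetrized and normalized to a fixed total."""
    if n_bins < 10:
        raise ValueError("need >= 10 bins")
    if decay_exponent >= 0:
        raise ValueError("decay_exponent must be negative")
    rng = np.random.default_rng(seed)
    d = bin_distance(n_bins, topology).astype(float)
    np.fill_diagonal(d, 1.0)                    # finite diagonal
    m = d ** decay_exponent
    if noise_sd > 0:
        noise = rng.lognormal(0.0, noise_sd, size=m.shape)
        noise = np.sqrt(noise * noise.T)        # keep symmetry
        m = m * noise
    m *= total / m.sum()
    return ContactMatrix(m, bin_size, topology)


def read_contact_tsv(path, bin_size: int = 10_000,
                     topology: str = "linear") -> ContactMatrix:
    """Read a contact matrix from dense TSV or 3-column COO TSV
    (bin_i, bin_j, count)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] == 3:
        n = int(max(df[0].max(), df[1].max())) + 1
        m = np.zeros((n, n))
        for i, j, v in df.itertuples(index=False, name=None):
            m[int(i), int(j)] = v
            m[int(j), int(i)] = v
        return ContactMatrix(m, bin_size, topology)
    return ContactMatrix(df.to_numpy(dtype=float), bin_size, topology)


def write_contact_tsv(cm: ContactMatrix, path, dense: bool = True) -> None:
    if dense:
        pd.DataFrame(cm.matrix).to_csv(path, sep="\t", header=False,
                                       index=False)
    else:
        iu = np.triu_indices(cm.n_bins)
        pd.DataFrame({"i": iu[0], "j": iu[1],
                      "count": cm.matrix[iu]}).to_csv(
            path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# event binning
# ---------------------------------------------------------------------------

def events_to_bin_pairs(events, ref, bin_size: int = 10_000,
                        n_bins: int | None = None) -> dict[tuple[int, int], int]:
    """Count events per (bin_a, bin_b) pair of their two recombination
    loci (unordered, bin_a <= bin_b)."""
    if n_bins is None:
        n_bins = (len(ref.sequence) + bin_size - 1) // bin_size
    counts: dict[tuple[int, int], int] = {}
    for ev in events:
        a, b = ev.loci
        if a is None or b is None:
            continue
        ba = min(ref.site_position(a) // bin_size, n_bins - 1)
        bb = min(ref.site_position(b) // bin_size, n_bins - 1)
        key = (min(ba, bb), max(ba, bb))
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# moving-average correlation
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    points: pd.DataFrame          # per-window means: contact, events
    r: float
    p: float
    slope: float
    intercept: float
    n_pairs_used: int

    @property
    def n_windows(self) -> int:
        return len(self.points)


def moving_average_correlation(event_counts: dict[tuple[int, int], int],
                               contacts: ContactMatrix,
                               window: int = 10, shift: int = 3,
                               drop: str = "either_zero",
                               include_diagonal: bool = False
                               ) -> CorrelationResult:
    """Moving-average Pearson correlation of event counts vs contacts.

    All upper-triangle bin pairs are annotated with event count and contact
    value; pairs with zero events or zero contacts are removed (``drop=
    "both_zero"`` keeps a pair unless both are zero); the rest are sorted
    ascending by contact; windows of ``window`` points advanced by ``shift``
    give per-window means on which r, the two-sided p-value, and the
    least-squares line are computed.  The result is independent of input
    ordering because the sort is internal.

    Within-bin pairs (the matrix diagonal) are excluded by default: the
    number of available locus pairs inside one bin scales quadratically
    differently from between-bin pairs, which would couple event counts to
    the contact-decay singularity even for recombination that is blind to
    chromosome conformation.
    """
    n = contacts.n_bins
    rows = []
    for i in range(n):
        for j in range(i if include_diagonal else i + 1, n):
            ev = event_counts.get((i, j), 0)
            c = contacts.matrix[i, j]
            rows.append((i, j, c, ev))
    df = pd.DataFrame(rows, columns=["i", "j", "contact", "events"])
    if drop == "either_zero":
        df = df[(df["events"] > 0) & (df["contact"] > 0)]
    elif drop == "both_zero":
        df = df[(df["events"] > 0) | (df["contact"] > 0)]
    else:
        raise ValueError(f"unknown drop mode {drop!r}")
    df = df.sort_values(["contact", "i", "j"], ignore_index=True)
    m = len(df)
    if m < window:
        raise ValueError(
            f"only {m} usable bin pairs for a window of {window}; "
            "use a smaller window")
    starts = range(0, m - window + 1, shift)
    pts = pd.DataFrame({
        "contact": [df["contact"].iloc[s:s + window].mean()
                    for s in starts],
        "events": [df["events"].iloc[s:s + window].mean()
                   for s in starts],
    })
    if pts["contact"].nunique() < 2 or pts["events"].nunique() < 2:
        r, p, slope, intercept = 0.0, 1.0, 0.0, float(pts["events"].mean())
    else:
        r, _p_naive = stats.pearsonr(pts["contact"], pts["events"])
        lr = stats.linregress(pts["contact"], pts["events"])
        slope, intercept = lr.slope, lr.intercept
        # consecutive window means share (window - shift) points, so the
        # smoothed series is strongly autocorrelated and the naive Pearson
        # p is anticonservative; the two-sided p is therefore computed with
        # an effective sample size of *non-overlapping* windows
        n_eff = (m - window) // window + 1
        if n_eff <= 2 or abs(r) >= 1:
            p = 1.0 if n_eff <= 2 else 0.0
        else:
            t = r * np.sqrt((n_eff - 2) / (1 - r * r))
            p = float(2 * stats.t.sf(abs(t), n_eff - 2))
    return CorrelationResult(pts, float(r), float(p), float(slope),
                             float(intercept), m)


# ---------------------------------------------------------------------------
# ROI bait profiles
# ---------------------------------------------------------------------------

def roi_bait_profile(contacts: ContactMatrix, roi: ROISpec) -> pd.DataFrame:
    """Mean normalized contact between the ROI bins (bait) and every
    non-ROI bin, indexed by genomic position."""
    roi.validate(contacts.n_bins)
    bait = sorted(roi.bins())
    rows = []
    for b in range(contacts.n_bins):
        if b in roi.bins():
            continue
        rows.append((b, b * contacts.bin_size,
                     float(contacts.matrix[bait, b].mean())))
    return pd.DataFrame(rows, columns=["bin", "position_bp", "contact"])


def roi_event_profile(events, ref, roi: ROISpec,
                      bin_size: int = 10_000,
                      n_bins: int | None = None) -> pd.DataFrame:
    """Count events joining the ROI to each non-ROI bin."""
    if n_bins is None:
        n_bins = (len(ref.sequence) + bin_size - 1) // bin_size
    roi.validate(n_bins)
    bait = roi.bins()
    counts = np.zeros(n_bins, dtype=int)
    for ev in events:
        a, b = ev.loci
        if a is None or b is None:
            continue
        ba = min(ref.site_position(a) // bin_size, n_bins - 1)
        bb = min(ref.site_position(b) // bin_size, n_bins - 1)
        for x, y in ((ba, bb), (bb, ba)):
            if x in bait and y not in bait:
                counts[y] += 1
    rows = [(b, b * bin_size, int(counts[b])) for b in range(n_bins)
            if b not in bait]
    return pd.DataFrame(rows, columns=["bin", "position_bp", "events"])


def correlation_plot(result: CorrelationResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(result.points["contact"], result.points["events"], s=12)
    xs = np.linspace(result.points["contact"].min(),
                     result.points["contact"].max(), 50)
    ax.plot(xs, result.slope * xs + result.intercept, color="red")
    ax.set_xlabel("contact strength (moving average)")
    ax.set_ylabel("events (moving average)")
    ax.set_title(f"r={result.r:.3f}, p={result.p:.2g}")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
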