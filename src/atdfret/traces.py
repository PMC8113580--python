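"""FRET computation, photobleach detection, trace selection, and histograms.

Implements the standard smFRET correction chain: the donor channel is scaled by
the detection-efficiency factor γ, then E = (IA − crosstalk·ID)/(ID + IA) is
evaluated on the corrected intensities.  Selection retains traces showing
single-donor and single-acceptor photobleaching with a stable total intensity
and at least 20 s of usable FRET; per-movie histograms are compiled from the
first 20 s of every selected trace, normalized per movie, and averaged across
movies with per-bin SEM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import PhotonTrace, TraceSet

DEFAULT_CROSSTALK = 0.105
DEFAULT_GAMMA = 1.1
HIST_RANGE = (-0.2, 1.2)
DEFAULT_BIN_WIDTH = 0.02

__all__ = [
    "FretTrace",
    "BleachRecord",
    "SelectionCriteria",
    "FretHistogram",
    "compute_fret",
    "detect_bleach_events",
    "subtract_background",
    "select_traces",
    "compile_histograms",
    "aggregate_histograms",
    "default_bin_edges",
]


@dataclass
class FretTrace:
    """Per-frame FRET efficiency; NaN where the total intensity is non-positive."""

    fret: np.ndarray
    frame_interval: float
    trace_id: str = ""
    movie_id: int = 0
    usable_frames: int | None = None  # frames before the first bleach event
    flags: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.fret)

    @property
    def usable(self) -> np.ndarray:
        """The FRET samples before the first bleach (whole trace if unknown)."""
        end = self.n_frames if self.usable_frames is None else self.usable_frames
        return self.fret[:end]


@dataclass
class BleachRecord:
    donor_frame: int | None
    acceptor_frame: int | None
    donor_steps: int
    acceptor_steps: int


@dataclass(frozen=True)
class SelectionCriteria:
    """Trace-selection thresholds.

    min_duration is the minimum span of usable FRET in seconds; the stability
    criterion bounds the coefficient of variation of the γ-corrected total
    intensity before the acceptor bleach.
    """

    min_duration: float = 20.0
    require_single_donor_bleach: bool = True
    require_single_acceptor_bleach: bool = True
    total_stability_cv_max: float = 0.15

    def __post_init__(self) -> None:
        if not self.min_duration > 0:
            raise ValueError("min_duration must be > 0")
        if not 0 < self.total_stability_cv_max < 1:
            raise ValueError("total_stability_cv_max must be in (0, 1)")


@dataclass
class FretHistogram:
    """Binned, normalized FRET density for one movie or a movie average."""

    bin_edges: np.ndarray
    density: np.ndarray
    n_molecules: int
    movie_id: int | None = None
    sem: np.ndarray | None = None
    condition: dict = field(default_factory=dict)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def default_bin_edges(bin_width: float = DEFAULT_BIN_WIDTH,
                      lo: float = HIST_RANGE[0], hi: float = HIST_RANGE[1]) -> np.ndarray:
    n = int(round((hi - lo) / bin_width))
    return lo + bin_width * np.arange(n + 1)


def compute_fret(trace: PhotonTrace, crosstalk: float = DEFAULT_CROSSTALK,
                 gamma: float = DEFAULT_GAMMA) -> FretTrace:
    """Corrected FRET efficiency per frame.

    The donor is first scaled by γ, then E = (IA − crosstalk·ID)/(ID + IA)
    using the corrected donor.  Frames with ID + IA ≤ 0 are NaN (undefined),
    never silently zero.
    """
    if not (np.isfinite(crosstalk) and np.isfinite(gamma) and gamma > 0):
        raise ValueError("crosstalk and gamma must be finite, gamma > 0")
    donor = np.asarray(trace.donor, dtype=float) * gamma
    acceptor = np.asarray(trace.acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor must have equal length")
    total = donor + acceptor
    fret = np.full_like(total, np.nan)
    ok = total > 0
    fret[ok] = (acceptor[ok] - crosstalk * donor[ok]) / total[ok]
    return FretTrace(fret=fret, frame_interval=trace.frame_interval,
                     trace_id=trace.trace_id, movie_id=trace.movie_id)


def _changepoint(x: np.ndarray, min_seg: int = 3) -> tuple[int | None, float]:
    """Exhaustive single change-point scan.

    Returns the split index k (start of the second segment) maximizing the
    between-segment mean difference normalized by the pooled variance
    (a two-sample t statistic), and that statistic.
    """
    n = len(x)
    if n < 2 * min_seg:
        return None, 0.0
    csum = np.cumsum(x)
    csum2 = np.cumsum(x * x)
    k = np.arange(min_seg, n - min_seg + 1)
    n1 = k.astype(float)
    n2 = n - n1
    s1 = csum[k - 1]
    s2 = csum[-1] - s1
    m1 = s1 / n1
    m2 = s2 / n2
    ss1 = csum2[k - 1] - n1 * m1**2
    ss2 = (csum2[-1] - csum2[k - 1]) - n2 * m2**2
    dof = np.maximum(n - 2, 1)
    pooled = np.sqrt(np.maximum(ss1 + ss2, 0.0) / dof)
    pooled = np.maximum(pooled, 1e-12)
    stat = np.abs(m1 - m2) / (pooled * np.sqrt(1.0 / n1 + 1.0 / n2))
    i = int(np.argmax(stat))
    return int(k[i]), float(stat[i])


def _recursive_changepoints(x: np.ndarray, threshold: float, min_seg: int) -> list[int]:
    """All change points found by recursive binary segmentation."""
    out: list[int] = []

    def _scan(lo: int, hi: int) -> None:
        k, stat = _changepoint(x[lo:hi], min_seg)
        if k is None or stat < threshold:
            return
        out.append(lo + k)
        _scan(lo, lo + k)
        _scan(lo + k, hi)

    _scan(0, len(x))
    return sorted(out)


def _bleach_steps(x: np.ndarray, threshold: float, min_seg: int,
                  baseline_frac: float) -> list[int]:
    """Change points that are downward steps to near-baseline.

    A detected step counts as a *bleach* step only when the segment level after
    it drops below ``baseline_frac`` of the maximum segment level; ordinary
    FRET state transitions change the channel level but never reach the
    post-bleach baseline.
    """
    cps = _recursive_changepoints(x, threshold, min_seg)
    if not cps:
        return []
    bounds = [0] + cps + [len(x)]
    means = np.array([x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])
    top = means.max()
    if top <= 0:
        return []
    steps = []
    for i, k in enumerate(cps):
        if means[i + 1] < means[i] and means[i + 1] < baseline_frac * top:
            steps.append(k)
    return steps


def detect_bleach_events(trace: PhotonTrace, crosstalk: float = DEFAULT_CROSSTALK,
                         gamma: float = DEFAULT_GAMMA, threshold: float = 8.0,
                         min_seg: int = 5, baseline_frac: float = 0.3) -> BleachRecord:
    """Locate donor and acceptor photobleach frames and count bleach steps.

    Donor bleaching is detected on the γ-corrected total intensity, which is
    conserved through FRET transitions and acceptor bleaching and falls to
    background only when the donor dies.  Acceptor bleaching is detected on
    the acceptor channel restricted to the pre-donor-bleach window, as the
    step down to the crosstalk-only baseline.
    """
    if trace.n_frames < 10:
        raise ValueError("trace must have at least 10 frames")
    total = gamma * np.asarray(trace.donor, float) + np.asarray(trace.acceptor, float)
    donor_steps = _bleach_steps(total, threshold, min_seg, baseline_frac)
    donor_frame = donor_steps[0] if donor_steps else None

    end = donor_frame if donor_frame is not None else trace.n_frames
    acc = np.asarray(trace.acceptor, float)[:end]
    acc_steps = _bleach_steps(acc, threshold, min_seg, baseline_frac)
    acceptor_frame = acc_steps[0] if acc_steps else None
    return BleachRecord(donor_frame=donor_frame, acceptor_frame=acceptor_frame,
                        donor_steps=len(donor_steps), acceptor_steps=len(acc_steps))


def subtract_background(trace: PhotonTrace, bleach: BleachRecord,
                        margin: int = 2) -> PhotonTrace:
    """Subtract the post-donor-bleach mean from each channel (identity if no bleach)."""
    if bleach.donor_frame is None or bleach.donor_frame + margin >= trace.n_frames:
        return trace
    sl = slice(bleach.donor_frame + margin, None)
    return PhotonTrace(
        donor=trace.donor - trace.donor[sl].mean(),
        acceptor=trace.acceptor - trace.acceptor[sl].mean(),
        frame_interval=trace.frame_interval, trace_id=trace.trace_id,
        movie_id=trace.movie_id, truth=trace.truth)


def select_traces(
    ts: TraceSet,
    crit: SelectionCriteria | None = None,
    crosstalk: float = DEFAULT_CROSSTALK,
    gamma: float = DEFAULT_GAMMA,
    background_subtract: bool = True,
) -> tuple[list[FretTrace], dict[str, str | None]]:
    """Apply the selection criteria; return usable FRET traces + rejection reasons.

    Every trace gets an entry in the reasons map: ``None`` if accepted,
    otherwise one of ``no_donor_bleach``, ``multistep_donor``,
    ``no_acceptor_bleach``, ``multistep_acceptor``, ``too_short``,
    ``unstable_total``.
    """
    crit = crit or SelectionCriteria()
    selected: list[FretTrace] = []
    reasons: dict[str, str | None] = {}
    for tr in ts.traces:
        reason = None
        try:
            bl = detect_bleach_events(tr, crosstalk, gamma)
        except ValueError:
            reasons[tr.trace_id] = "too_short"
            continue
        if crit.require_single_donor_bleach:
            if bl.donor_steps == 0:
                reason = "no_donor_bleach"
            elif bl.donor_steps > 1:
                reason = "multistep_donor"
        if reason is None and crit.require_single_acceptor_bleach:
            if bl.acceptor_steps == 0:
                reason = "no_acceptor_bleach"
            elif bl.acceptor_steps > 1:
                reason = "multistep_acceptor"

        ends = [f for f in (bl.acceptor_frame, bl.donor_frame) if f is not None]
        usable = max(min(ends) - 1, 0) if ends else tr.n_frames
        if reason is None and usable * ts.frame_interval < crit.min_duration:
            reason = "too_short"
        if reason is None and usable >= 2:
            total = gamma * tr.donor[:usable] + tr.acceptor[:usable]
            mean = total.mean()
            cv = float(total.std() / mean) if mean > 0 else np.inf
            if cv > crit.total_stability_cv_max:
                reason = "unstable_total"

        reasons[tr.trace_id] = reason
        if reason is None:
            src = subtract_background(tr, bl) if background_subtract else tr
            ft = compute_fret(src, crosstalk, gamma)
            ft.usable_frames = usable
            ft.flags = {"donor_frame": bl.donor_frame, "acceptor_frame": bl.acceptor_frame}
            selected.append(ft)
    return selected, reasons


def compile_histograms(
    fts: list[FretTrace],
    window: float = 20.0,
    bin_edges: np.ndarray | None = None,
    condition: dict | None = None,
) -> list[FretHistogram]:
    """Per-movie normalized histograms from the first ``window`` seconds of each trace.

    Movies contributing zero frames are excluded (with a warning).  Each
    histogram integrates to 1 over its binning range.
    """
    import warnings

    edges = default_bin_edges() if bin_edges is None else np.asarray(bin_edges, float)
    by_movie: dict[int, list[FretTrace]] = {}
    for ft in fts:
        by_movie.setdefault(ft.movie_id, []).append(ft)
    out = []
    for movie_id in sorted(by_movie):
        samples = []
        n_mol = 0
        for ft in by_movie[movie_id]:
            n = min(int(round(window / ft.frame_interval)), len(ft.usable))
            vals = ft.usable[:n]
            vals = vals[np.isfinite(vals)]
            if len(vals):
                samples.append(vals)
                n_mol += 1
        if not samples:
            warnings.warn(f"movie {movie_id}: no usable frames, excluded")
            continue
        data = np.concatenate(samples)
        counts, _ = np.histogram(data, bins=edges)
        width = edges[1] - edges[0]
        density = counts / (counts.sum() * width)
        out.append(FretHistogram(bin_edges=edges, density=density, n_molecules=n_mol,
                                 movie_id=movie_id, condition=dict(condition or {})))
    return out


def aggregate_histograms(hists: list[FretHistogram]) -> FretHistogram:
    """Bin-wise mean ± SEM across per-movie histograms."""
    if not hists:
        raise ValueError("no histograms to aggregate")
    edges = hists[0].bin_edges
    for h in hists[1:]:
        if not np.allclose(h.bin_edges, edges):
            raise ValueError("histograms must share bin edges")
    dens = np.vstack([h.density for h in hists])
    mean = dens.mean(axis=0)
    sem = dens.std(axis=0, ddof=1) / np.sqrt(len(hists)) if len(hists) > 1 else np.zeros_like(mean)
    return FretHistogram(bin_edges=edges, density=mean,
                         n_molecules=sum(h.n_molecules for h in hists),
                         movie_id=None, sem=sem, condition=dict(hists[0].condition))
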