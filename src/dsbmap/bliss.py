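"""BLISS cut-site quantification and ranking.

BLISS (breaks labelling in situ and sequencing) reads mark DSB ends with
their 5' extremities. This module filters reads by linker barcode, removes
UMI duplicates, quantifies each restriction-site window with the covered
fraction (cf) and read coverage (rc), applies local (ln = rc/cf), global
(gn = ln/median ln) and quantile (qn) normalization, and ranks sites by the
log2 ratio of induced over uninduced qn counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .digest import GenomicWindow, RestrictionSite

logger = logging.getLogger(__name__)

_READ_ALPHABET = set("ACGTN")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read (or read-start interval), 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    barcode: str | None = None
    umi: str | None = None
    mate_span: tuple[int, int] | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"read span must satisfy start < end: {self}")
        for tag in (self.barcode, self.umi):
            if tag is not None and (set(tag) - _READ_ALPHABET):
                raise ValueError(f"barcode/UMI must be over A/C/G/T/N: {tag!r}")

    @property
    def five_prime(self) -> int:
        """Position of the 5' end (break-proximal end for BLISS reads)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def span(self) -> tuple[int, int]:
        """Full fragment span when mates are known, else the read span."""
        return self.mate_span if self.mate_span is not None else (self.start, self.end)


class FilterResult(NamedTuple):
    reads: list[ReadRecord]
    n_input: int
    n_barcode_dropped: int
    n_duplicates_removed: int


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def filter_reads(
    reads: Iterable[ReadRecord],
    expected_barcode: str | None = None,
    max_mismatch: int = 0,
    dedup: bool = False,
) -> FilterResult:
    """Barcode-filter and UMI-deduplicate a read set.

    Reads whose barcode differs from ``expected_barcode`` by more than
    ``max_mismatch`` positions (or has the wrong length, or is absent) are
    dropped and counted. Deduplication collapses reads sharing
    ``(chrom, start, strand, umi)`` to a single record.
    """
    if expected_barcode is not None and not expected_barcode:
        raise ValueError("expected_barcode must be non-empty when filtering")
    kept: list[ReadRecord] = []
    n_input = 0
    n_barcode = 0
    for read in reads:
        n_input += 1
        if expected_barcode is not None:
            if read.barcode is None or len(read.barcode) != len(expected_barcode):
                n_barcode += 1
                continue
            if hamming(read.barcode, expected_barcode) > max_mismatch:
                n_barcode += 1
                continue
        kept.append(read)
    n_dups = 0
    if dedup:
        seen: set[tuple] = set()
        unique = []
        for read in kept:
            key = (read.chrom, read.start, read.strand, read.umi)
            if key in seen:
                n_dups += 1
                continue
            seen.add(key)
            unique.append(read)
        kept = unique
    if n_input and not kept:
        warnings.warn("all reads dropped by filtering", stacklevel=2)
    return FilterResult(kept, n_input, n_barcode, n_dups)


def _union_overlap(spans: list[tuple[int, int]], start: int, end: int) -> int:
    """Total bp of [start, end) covered by the union of spans."""
    clipped = sorted(
        (max(s, start), min(e, end)) for s, e in spans if s < end and e > start
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def quantify_site(
    window: GenomicWindow,
    reads: Sequence[ReadRecord],
    mode: str = "starts",
) -> tuple[float, float]:
    """Covered fraction and read coverage of one site window.

    cf is the fraction of window bases overlapped by at least one read
    (fragment spans when mates are known). rc in ``"starts"`` mode counts
    reads whose 5' end lies inside the window — the natural BLISS proxy for
    break ends. The alternative ``"pileup-origin"`` mode sums the per-base
    depth inside the window contributed by window-originating reads.
    """
    length = window.end - window.start
    if length <= 0:
        raise ValueError("zero-length window")
    if mode not in ("starts", "pileup-origin"):
        raise ValueError(f"unknown rc mode {mode!r}")
    on_chrom = [r for r in reads if r.chrom == window.chrom]
    spans = [r.span for r in on_chrom]
    cf = _union_overlap(spans, window.start, window.end) / length
    origin = [r for r in on_chrom if window.start <= r.five_prime < window.end]
    if mode == "starts":
        rc = float(len(origin))
    else:
        rc = 0.0
        for r in origin:
            s, e = r.span
            rc += max(0, min(e, window.end) - max(s, window.start))
    return cf, rc


class _ChromIndex:
    """Sorted per-chromosome read arrays for fast window queries."""

    def __init__(self, reads: Sequence[ReadRecord]):
        by_chrom: dict[str, list[ReadRecord]] = {}
        for r in reads:
            by_chrom.setdefault(r.chrom, []).append(r)
        self.data = {}
        for chrom, rs in by_chrom.items():
            spans = np.array([r.span for r in rs], dtype=np.int64)
            order = np.argsort(spans[:, 0], kind="stable")
            spans = spans[order]
            fives = np.array([rs[i].five_prime for i in order], dtype=np.int64)
            max_len = int((spans[:, 1] - spans[:, 0]).max()) if len(rs) else 0
            self.data[chrom] = (spans, np.sort(fives), max_len)

    def query(self, window: GenomicWindow):
        """(overlapping spans, count of 5' ends in window, span list) for one window."""
        if window.chrom not in self.data:
            return np.empty((0, 2), dtype=np.int64), 0
        spans, fives, max_len = self.data[window.chrom]
        lo = np.searchsorted(spans[:, 0], window.start - max_len, side="left")
        hi = np.searchsorted(spans[:, 0], window.end, side="left")
        cand = spans[lo:hi]
        cand = cand[cand[:, 1] > window.start]
        n5 = int(
            np.searchsorted(fives, window.end, side="left")
            - np.searchsorted(fives, window.start, side="left")
        )
        return cand, n5


def quantify_library(
    windows: Sequence[GenomicWindow],
    site_ids: Sequence[str],
    reads: Sequence[ReadRecord],
    mode: str = "starts",
) -> pd.DataFrame:
    """Per-site (cf, rc) table for one library, indexed by site_id."""
    if len(windows) != len(site_ids):
        raise ValueError("windows and site_ids must align")
    index = _ChromIndex(reads)
    rows = []
    for sid, win in zip(site_ids, windows):
        length = win.end - win.start
        if length <= 0:
            raise ValueError(f"zero-length window for site {sid}")
        spans, n5 = index.query(win)
        cf = _union_overlap([tuple(s) for s in spans], win.start, win.end) / length
        if mode == "starts":
            rc = float(n5)
        else:
            origins = [
                r
                for r in reads
                if r.chrom == win.chrom and win.start <= r.five_prime < win.end
            ]
            rc = float(
                sum(
                    max(0, min(r.span[1], win.end) - max(r.span[0], win.start))
                    for r in origins
                )
            )
        rows.append((sid, cf, rc, n5))
    return pd.DataFrame(
        rows, columns=["site_id", "cf", "rc", "n_origin"]
    ).set_index("site_id")


def normalize_local_global(
    quants: pd.DataFrame,
    degenerate: str = "error",
) -> pd.DataFrame:
    """Add locally (ln = rc/cf) and globally (gn = ln/median ln) normalized counts.

    ln at cf = 0 is defined as 0 (rc is necessarily 0 there: no evidence).
    The median uses midpoint interpolation, which preserves median(gn) = 1
    exactly. A library whose median ln is 0 carries no signal at the
    inspected sites; by default that raises, but ``degenerate="passthrough"``
    keeps gn = ln so that a background-only control library can still flow
    through ratio ranking.
    """
    if len(quants) == 0:
        raise ValueError("need at least one site")
    out = quants.copy()
    cf = out["cf"].to_numpy(float)
    rc = out["rc"].to_numpy(float)
    if (cf < 0).any() or (cf > 1).any():
        raise ValueError("cf must lie in [0, 1]")
    if (rc < 0).any():
        raise ValueError("rc must be non-negative")
    ln = np.where(cf > 0, rc / np.where(cf > 0, cf, 1.0), 0.0)
    med = float(np.median(ln))
    if med == 0:
        if degenerate == "error":
            raise ValueError("degenerate library: no signal at inspected sites")
        logger.warning(
            "degenerate library (median ln = 0); global normalization skipped"
        )
        gn = ln.copy()
    else:
        gn = ln / med
    out["ln"] = ln
    out["gn"] = gn
    return out


def quantile_normalize_pair(
    induced: Sequence[float], uninduced: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Map the induced distribution, rank for rank, onto the uninduced one.

    The highest induced entry takes the value of the highest uninduced entry
    and so on; the uninduced vector is returned unchanged. Tied induced
    entries receive the mean of the uninduced values at the tied ranks (so
    equal inputs stay equal; note that averaging over ties is the one case
    where the sorted multisets of the two outputs can differ).
    """
    ind = np.asarray(induced, dtype=float)
    unind = np.asarray(uninduced, dtype=float)
    if ind.shape != unind.shape or ind.ndim != 1:
        raise ValueError("vectors must be 1-D and of equal length")
    if ind.size == 0:
        raise ValueError("empty vectors")
    order = np.argsort(ind, kind="stable")
    qn = np.empty_like(ind)
    qn[order] = np.sort(unind)
    qn = pd.Series(qn).groupby(pd.Series(ind)).transform("mean").to_numpy()
    return qn, unind.copy()


@dataclass(frozen=True)
class CutSiteCall:
    site_id: str
    ratio: float
    log2ratio: float
    rank: int
    called: bool


def rank_cut_sites(
    quants: pd.DataFrame,
    pseudocount: float = 1.0,
    min_induced_rc: int = 3,
    log2ratio_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Rank sites by induced/uninduced qn ratio and call enriched ones.

    ``quants`` must carry columns qn_induced, qn_uninduced, rc_induced,
    chrom, motif_start, indexed by site_id. ratio = (qn_i + eps)/(qn_u + eps);
    sites are sorted by descending log2ratio with ties broken by
    (chrom, motif_start); called = log2ratio >= cutoff and the raw induced
    read count >= min_induced_rc (column n_origin_induced when present —
    needed when rc is a per-base pileup rather than a read count — else
    rc_induced).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    required = {"qn_induced", "qn_uninduced", "rc_induced", "chrom", "motif_start"}
    missing = required - set(quants.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (quants["qn_induced"] < 0).any() or (quants["qn_uninduced"] < 0).any():
        raise ValueError("negative qn values")
    out = quants.copy()
    out["ratio"] = (out["qn_induced"] + pseudocount) / (
        out["qn_uninduced"] + pseudocount
    )
    out["log2ratio"] = np.log2(out["ratio"])
    out = out.sort_values(
        ["log2ratio", "chrom", "motif_start"], ascending=[False, True, True]
    )
    out["rank"] = np.arange(1, len(out) + 1)
    read_count = out.get("n_origin_induced", out["rc_induced"])
    out["called"] = (out["log2ratio"] >= log2ratio_cutoff) & (
        read_count >= min_induced_rc
    )
    return out


def call_cut_sites(
    sites: Sequence[RestrictionSite],
    windows: Sequence[GenomicWindow],
    reads_induced: Sequence[ReadRecord],
    reads_uninduced: Sequence[ReadRecord],
    mode: str = "pileup-origin",
    pseudocount: float = 1.0,
    min_induced_rc: int = 3,
    log2ratio_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Full per-site chain: quantify both libraries, normalize, rank, call.

    The default rc mode is "pileup-origin" (summed per-base depth from
    window-originating reads): with read-count rc, a lone read that clips a
    window edge yields a tiny cf and an exploding ln = rc/cf, whereas under
    pileup rc the overlap cancels (one read gives ln = window length
    regardless of clipping), which keeps sparse background libraries from
    producing spurious top ranks. The min-read call filter always uses the
    raw count of window-originating reads (n_origin).

    When one library is degenerate (median ln = 0, e.g. a background-only
    uninduced control) both libraries are scaled by the companion's median
    ln and quantile normalization is skipped, because rank-mapping onto a
    near-empty distribution would erase the induced signal.
    """
    site_ids = [s.site_id for s in sites]
    qi = normalize_local_global(
        quantify_library(windows, site_ids, reads_induced, mode=mode),
        degenerate="passthrough",
    )
    qu = normalize_local_global(
        quantify_library(windows, site_ids, reads_uninduced, mode=mode),
        degenerate="passthrough",
    )
    med_i = float(np.median(qi["ln"]))
    med_u = float(np.median(qu["ln"]))
    if med_u == 0.0 or med_i == 0.0:
        # One library carries no signal at the inspected sites (e.g. a
        # background-only uninduced control). Its own median cannot set the
        # global scale, so both libraries are put on the companion's scale
        # (gn = ln / median of the non-degenerate library), and quantile
        # normalization is skipped: rank-mapping onto a near-empty
        # distribution would erase the induced signal.
        shared = med_i or med_u
        logger.warning(
            "degenerate library (median ln = 0); using shared scale %.3g "
            "and skipping quantile normalization", shared,
        )
        if shared > 0:
            qi["gn"] = qi["ln"] / shared
            qu["gn"] = qu["ln"] / shared
        qn_i, qn_u = qi["gn"].to_numpy(), qu["gn"].to_numpy()
    else:
        qn_i, qn_u = quantile_normalize_pair(
            qi["gn"].to_numpy(), qu["gn"].to_numpy()
        )
    table = pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "motif_start": [s.motif_start for s in sites],
            "center": [s.center for s in sites],
            "cf_induced": qi["cf"].to_numpy(),
            "rc_induced": qi["rc"].to_numpy(),
            "n_origin_induced": qi["n_origin"].to_numpy(),
            "n_origin_uninduced": qu["n_origin"].to_numpy(),
            "ln_induced": qi["ln"].to_numpy(),
            "gn_induced": qi["gn"].to_numpy(),
            "qn_induced": qn_i,
            "cf_uninduced": qu["cf"].to_numpy(),
            "rc_uninduced": qu["rc"].to_numpy(),
            "ln_uninduced": qu["ln"].to_numpy(),
            "gn_uninduced": qu["gn"].to_numpy(),
            "qn_uninduced": qn_u,
        },
        index=pd.Index(site_ids, name="site_id"),
    )
    return rank_cut_sites(
        table,
        pseudocount=pseudocount,
        min_induced_rc=min_induced_rc,
        log2ratio_cutoff=log2ratio_cutoff,
    )
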