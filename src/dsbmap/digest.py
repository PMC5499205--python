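"""In silico restriction digestion.

Scans genome sequences for a restriction-enzyme recognition motif (default
AsiSI, 5'-GCGATCGC-3') and builds symmetric quantification windows around each
occurrence. The AsiSI motif is an 8-bp palindrome, so a single forward-strand
scan enumerates every genomic recognition occurrence; overlapping occurrences
are all reported, as digestion is defined per recognition occurrence.

Coordinates are 0-based half-open throughout; conversion to other conventions
happens only at I/O boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import pandas as pd

#: AsiSI recognition sequence (palindromic).
ASISI_MOTIF = "GCGATCGC"

#: Chromosomes counted as "reference" for the GRCh37/hg19 assembly; every
#: other FASTA record is treated as a haplotype or unplaced contig.
REFERENCE_CHROMS = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY", "chrM"]
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RestrictionSite:
    """A genomic locus matching the recognition motif on the forward strand."""

    chrom: str
    motif_start: int
    motif_end: int
    center: int
    site_id: str

    @staticmethod
    def from_match(chrom: str, start: int, motif_len: int) -> "RestrictionSite":
        return RestrictionSite(
            chrom=chrom,
            motif_start=start,
            motif_end=start + motif_len,
            center=start + motif_len // 2,
            site_id=f"{chrom}:{start}",
        )


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open interval around a site center; ``clipped`` marks boundary truncation."""

    chrom: str
    start: int
    end: int
    clipped: bool


def _validate_motif(motif: str, allow_ambiguity: bool) -> str:
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    allowed = set(_IUPAC) if allow_ambiguity else set("ACGT")
    bad = set(motif) - allowed
    if bad:
        raise ValueError(
            f"motif contains characters outside the allowed alphabet: {sorted(bad)}"
        )
    return motif


def motif_pattern(motif: str, allow_ambiguity: bool = False) -> re.Pattern:
    """Compile a case-insensitive, overlap-aware regex for a nucleotide motif."""
    motif = _validate_motif(motif, allow_ambiguity)
    parts = []
    for base in motif:
        opts = _IUPAC[base]
        parts.append(base if len(opts) == 1 else f"[{opts}]")
    # lookahead so overlapping occurrences are all reported
    return re.compile("(?=(" + "".join(parts) + "))", re.IGNORECASE)


def _iter_sequences(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
) -> Iterator[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        yield from sequences.items()
    else:
        yield from sequences


def find_restriction_sites(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    motif: str = ASISI_MOTIF,
    allow_ambiguity: bool = False,
) -> list[RestrictionSite]:
    """Enumerate every forward-strand motif occurrence in a genome.

    Matching is case-insensitive (soft-masked lowercase bases match) and
    overlap-aware. ``sequences`` may be a dict or a streaming iterable of
    ``(name, sequence)`` pairs, which keeps memory flat for assembly-scale
    genomes. Results are sorted by ``(chrom, motif_start)``.
    """
    pattern = motif_pattern(motif, allow_ambiguity)
    motif_len = len(motif)
    sites: list[RestrictionSite] = []
    n_records = 0
    for chrom, seq in _iter_sequences(sequences):
        n_records += 1
        for m in pattern.finditer(seq):
            sites.append(RestrictionSite.from_match(chrom, m.start(), motif_len))
    if n_records == 0:
        raise ValueError("empty genome: no sequences provided")
    sites.sort(key=lambda s: (s.chrom, s.motif_start))
    return sites


def make_site_windows(
    sites: Iterable[RestrictionSite],
    flank: int,
    chrom_lengths: Mapping[str, int],
) -> list[GenomicWindow]:
    """Build the ``[center - flank, center + flank)`` window for each site.

    Windows are clipped at chromosome boundaries; the ``clipped`` flag records
    truncation. One window per site, in site order.
    """
    if flank <= 0:
        raise ValueError(f"flank must be positive, got {flank}")
    windows = []
    for site in sites:
        if site.chrom not in chrom_lengths:
            raise ValueError(f"chromosome {site.chrom!r} missing from chrom_lengths")
        length = chrom_lengths[site.chrom]
        if site.motif_end > length:
            raise ValueError(
                f"site {site.site_id} extends beyond chromosome length {length}"
            )
        start = site.center - flank
        end = site.center + flank
        clipped = start < 0 or end > length
        windows.append(
            GenomicWindow(site.chrom, max(start, 0), min(end, length), clipped)
        )
    return windows


def site_density(
    sites: Iterable[RestrictionSite],
    chrom_lengths: Mapping[str, int],
) -> dict:
    """Sites per Mb, pooled and per chromosome.

    The pooled density divides the total site count by the total genome size;
    the per-chromosome mean averages each chromosome's own density. Both are
    reported because either averaging scheme is defensible.
    """
    if not chrom_lengths:
        raise ValueError("empty chrom_lengths")
    if any(length <= 0 for length in chrom_lengths.values()):
        raise ValueError("chromosome lengths must be positive")
    counts = {chrom: 0 for chrom in chrom_lengths}
    total = 0
    for site in sites:
        counts[site.chrom] += 1
        total += 1
    per_chrom = pd.DataFrame(
        {
            "chrom": list(chrom_lengths),
            "length_bp": [chrom_lengths[c] for c in chrom_lengths],
            "n_sites": [counts[c] for c in chrom_lengths],
        }
    )
    per_chrom["sites_per_mb"] = per_chrom["n_sites"] / (per_chrom["length_bp"] / 1e6)
    total_bp = per_chrom["length_bp"].sum()
    return {
        "per_chrom": per_chrom,
        "pooled_per_mb": total / (total_bp / 1e6),
        "per_chrom_mean": float(per_chrom["sites_per_mb"].mean()),
        "n_sites": total,
    }


def split_reference_sites(
    sites: Iterable[RestrictionSite],
    reference_chroms: frozenset[str] | set[str] = REFERENCE_CHROMS,
) -> tuple[list[RestrictionSite], list[RestrictionSite]]:
    """Partition sites into (reference-chromosome, haplotype/unplaced) lists."""
    ref, other = [], []
    for site in sites:
        (ref if site.chrom in reference_chroms else other).append(site)
    return ref, other
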