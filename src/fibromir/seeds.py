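"""Canonical miRNA seed-match scanning of 3'UTR sequences.

The seed is miRNA nucleotides 2-8 (5'->3').  On the UTR sense strand the
four canonical site classes are, 5'->3':

    8mer      rc(seed 2-8) followed by A   (8 nt; the A pairs position 1)
    7mer-m8   rc(seed 2-8)                 (7 nt)
    7mer-A1   rc(seed 2-7) followed by A   (7 nt)
    6mer      rc(seed 2-7)                 (6 nt)

Only perfect Watson-Crick matches are considered (no wobble pairing, no
context scoring).  Coordinates are 1-based inclusive on the sense strand;
an explicit converter to BED (0-based half-open) is provided.  Overlapping
calls at one locus are resolved to the strongest class
(8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

__all__ = [
    "SITE_TYPES",
    "SeedSite",
    "site_sequence",
    "seed_sites",
    "mutate_and_rescan",
    "MutationRescan",
    "to_bed",
]

#: canonical site classes, strongest first
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")

_VALID = set("ACGT")


def _normalize(seq: str, what: str) -> str:
    """Uppercase DNA alphabet (U accepted as T)."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _VALID
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class SeedSite:
    """A seed-match interval on a UTR (1-based inclusive, sense strand)."""

    utr_id: str
    start: int
    end: int
    site_type: str
    sequence: str

    def __post_init__(self):
        if self.end - self.start + 1 != {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}[
            self.site_type
        ]:
            raise ValueError("site span inconsistent with its type")


def site_sequence(mirna_seq: str, site_type: str) -> str:
    """The exact UTR sequence (DNA, sense strand) a site class must show."""
    m = _normalize(mirna_seq, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA sequence must be >= 8 nt")
    if site_type not in SITE_TYPES:
        raise ValueError(f"unknown site type {site_type!r}")
    rc_2_8 = str(Seq(m[1:8]).reverse_complement())  # seed positions 2-8
    rc_2_7 = str(Seq(m[1:7]).reverse_complement())  # seed positions 2-7
    return {
        "8mer": rc_2_8 + "A",
        "7mer-m8": rc_2_8,
        "7mer-A1": rc_2_7 + "A",
        "6mer": rc_2_7,
    }[site_type]


def seed_sites(mirna_seq: str, utr_seq: str, utr_id: str = "utr") -> list[SeedSite]:
    """All maximal canonical seed sites of a miRNA on a UTR, sorted by start.

    Every UTR position belongs to at most one reported site: candidate
    matches of all four classes are collected and overlaps resolved in
    favour of the strongest class (then the leftmost start).
    """
    utr = _normalize(utr_seq, "UTR")
    patterns = {t: site_sequence(mirna_seq, t) for t in SITE_TYPES}

    candidates: list[tuple[int, int, SeedSite]] = []
    for strength, t in enumerate(SITE_TYPES):
        pat = patterns[t]
        start = utr.find(pat)
        while start != -1:
            site = SeedSite(
                utr_id=utr_id,
                start=start + 1,
                end=start + len(pat),
                site_type=t,
                sequence=pat,
            )
            candidates.append((strength, start, site))
            start = utr.find(pat, start + 1)

    chosen: list[SeedSite] = []
    occupied: set[int] = set()
    for _, _, site in sorted(candidates, key=lambda c: (c[0], c[1])):
        span = range(site.start, site.end + 1)
        if occupied.isdisjoint(span):
            chosen.append(site)
            occupied.update(span)
    return sorted(chosen, key=lambda s: s.start)


@dataclass
class MutationRescan:
    """Sites before and after point mutations of a UTR."""

    before: list[SeedSite]
    after: list[SeedSite]
    mutated_utr: str

    @property
    def lost(self) -> list[SeedSite]:
        return [s for s in self.before if s not in self.after]

    @property
    def gained(self) -> list[SeedSite]:
        return [s for s in self.after if s not in self.before]


def mutate_and_rescan(
    mirna_seq: str,
    utr_seq: str,
    edits: list[tuple[int, str]],
    utr_id: str = "utr",
) -> MutationRescan:
    """Apply point substitutions (1-based positions) and re-scan for sites."""
    utr = _normalize(utr_seq, "UTR")
    bases = list(utr)
    for pos, base in edits:
        if not 1 <= pos <= len(bases):
            raise ValueError(f"edit position {pos} outside UTR of length {len(bases)}")
        bases[pos - 1] = _normalize(base, "edit base")
    mutated = "".join(bases)
    return MutationRescan(
        before=seed_sites(mirna_seq, utr, utr_id),
        after=seed_sites(mirna_seq, mutated, utr_id),
        mutated_utr=mutated,
    )


def to_bed(sites: list[SeedSite]) -> str:
    """Sites as BED lines (0-based half-open), one per site."""
    return "\n".join(
        f"{s.utr_id}\t{s.start - 1}\t{s.end}\t{s.site_type}\t0\t+" for s in sites
    )
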