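"""Genome-wide enumeration of spacer sites adjacent to NGG/NAG PAMs.

A spacer site is a 20-nt protospacer immediately 5' of a 3-nt PAM on either
strand.  5'-NGG-3' is the canonical SpCas9 PAM; 5'-NAG-3' is the alternative
PAM that is scanned only to supply potential off-target loci, never to
propose guide candidates.  Overlapping sites are all reported; any window
whose protospacer or PAM contains a literal N is skipped, since an N can
neither confirm nor deny a difference.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .sequence_io import Genome, Interval, reverse_complement

PAM_NGG = "NGG"
PAM_NAG = "NAG"

# Forward-strand regexes; the minus strand is scanned as the reverse
# complement pattern on the forward sequence (CCN for NGG, CTN for NAG).
_FWD_PATTERNS = {PAM_NGG: re.compile(r"(?=[ACGT]GG)"), PAM_NAG: re.compile(r"(?=[ACGT]AG)")}
_REV_PATTERNS = {PAM_NGG: re.compile(r"(?=CC[ACGT])"), PAM_NAG: re.compile(r"(?=CT[ACGT])")}


@dataclass(frozen=True)
class SpacerSite:
    """One protospacer occurrence: 20-nt window + adjacent PAM on one strand.

    ``protospacer`` and ``pam`` are given 5'->3' in the orientation of the
    site's strand; the PAM is immediately 3' of the protospacer.  ``interval``
    covers the protospacer only (PAM excluded) in forward-genome coordinates.
    """

    interval: Interval
    protospacer: str
    pam: str
    pam_class: str
    spacer_len: int = 20

    def __post_init__(self) -> None:
        if len(self.protospacer) != self.spacer_len:
            raise ValueError("protospacer length does not match spacer_len")
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")
        if self.pam_class not in (PAM_NGG, PAM_NAG):
            raise ValueError(f"unknown PAM class {self.pam_class!r}")
        expected = "GG" if self.pam_class == PAM_NGG else "AG"
        if self.pam[1:] != expected:
            raise ValueError(f"PAM {self.pam!r} does not match class {self.pam_class}")

    @property
    def strand(self) -> str:
        return self.interval.strand

    def key(self) -> tuple[str, int, int, str]:
        """Identity of the site: (seq_name, start, end, strand)."""
        iv = self.interval
        return (iv.seq_name, iv.start, iv.end, iv.strand)


def scan_pam_sites(
    genome: Genome,
    pam_classes: frozenset[str] | set[str] = frozenset({PAM_NGG}),
    spacer_len: int = 20,
) -> list[SpacerSite]:
    """Enumerate every spacer site of the requested PAM classes on both strands.

    Returns sites sorted by (seq_name, start, strand).  Windows containing N
    (in the protospacer or the PAM) are omitted.
    """
    if spacer_len < 10:
        raise ValueError("spacer_len must be >= 10")
    unknown = set(pam_classes) - {PAM_NGG, PAM_NAG}
    if unknown:
        raise ValueError(f"unknown PAM classes: {sorted(unknown)}")
    if not genome.records:
        raise ValueError("genome has no sequences")

    sites: list[SpacerSite] = []
    for name, seq in genome.records.items():
        L = len(seq)
        for pam_class in sorted(pam_classes):
            # Plus strand: PAM at [p, p+3), protospacer at [p-spacer_len, p).
            for m in _FWD_PATTERNS[pam_class].finditer(seq):
                p = m.start()
                if p < spacer_len:
                    continue
                proto = seq[p - spacer_len : p]
                if "N" in proto:
                    continue
                sites.append(
                    SpacerSite(
                        interval=Interval(name, p - spacer_len, p, "+"),
                        protospacer=proto,
                        pam=seq[p : p + 3],
                        pam_class=pam_class,
                        spacer_len=spacer_len,
                    )
                )
            # Minus strand: forward pattern is the reverse complement of the
            # PAM; the protospacer lies at higher forward coordinates.
            for m in _REV_PATTERNS[pam_class].finditer(seq):
                p = m.start()
                if p + 3 + spacer_len > L:
                    continue
                proto_fwd = seq[p + 3 : p + 3 + spacer_len]
                if "N" in proto_fwd:
                    continue
                sites.append(
                    SpacerSite(
                        interval=Interval(name, p + 3, p + 3 + spacer_len, "-"),
                        protospacer=reverse_complement(proto_fwd),
                        pam=reverse_complement(seq[p : p + 3]),
                        pam_class=pam_class,
                        spacer_len=spacer_len,
                    )
                )
    sites.sort(key=lambda s: (s.interval.seq_name, s.interval.start, s.interval.strand))
    return sites


def collect_unique_spacers(sites: list[SpacerSite]) -> dict[str, list[SpacerSite]]:
    """Group sites by protospacer sequence.

    A spacer sequence occurring at multiple loci is intrinsically non-specific
    (each copy is a perfect off-target of the others), so downstream
    classification must see all copies.
    """
    groups: dict[str, list[SpacerSite]] = {}
    for site in sites:
        groups.setdefault(site.protospacer, []).append(site)
    return groups
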