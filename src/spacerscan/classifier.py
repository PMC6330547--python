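"""Seed-region specificity classification of spacers.

Spacers are classified into eight classes ordered by specificity:
A0, B0, A0.1, B0.1, A1, B1, A2, B2 (rank 1 = most specific), or rejected.

NGG off-targets decide the group: group A requires every NGG hit to carry at
least one difference inside the 10-nt PAM-proximal seed; group B requires at
least one difference inside the 15-nt seed plus three or more differences
overall.  A spacer whose NGG hits satisfy neither criterion is rejected —
every admitted spacer therefore has sufficient specificity against NGG
sites.  The NAG subclass then grades residual off-target potential at
alternative-PAM (NAG) sites with the analogous rules: 0 and 0.1 mirror the
A and B criteria, 1 admits NAG sites with two differences anywhere, and 2
marks a near-perfect NAG site (at most one difference).  Classes A0–B0.1
provide sufficient differences to both NGG and NAG targets; A1–B2 may have
NAG off-targets and are recommended only when no higher class is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .offtarget_engine import (
    OffTargetHit,
    OffTargetSearcher,
    SearchParams,
)
from .pam_scanner import PAM_NAG, PAM_NGG, SpacerSite, scan_pam_sites
from .sequence_io import Annotation, Genome

REJECTED = "REJECTED"

GROUP_A = "A"
GROUP_B = "B"

#: Fixed class order, most to least specific.
CLASS_ORDER = ("A0", "B0", "A0.1", "B0.1", "A1", "B1", "A2", "B2")

_SUBCLASS_LABEL = {0: "0", 0.1: "0.1", 1: "1", 2: "2"}


@dataclass(frozen=True)
class SpacerClass:
    group: str
    nag_subclass: float

    def __post_init__(self) -> None:
        if self.group not in (GROUP_A, GROUP_B):
            raise ValueError(f"invalid group {self.group!r}")
        if self.nag_subclass not in _SUBCLASS_LABEL:
            raise ValueError(f"invalid NAG subclass {self.nag_subclass!r}")

    @property
    def label(self) -> str:
        return f"{self.group}{_SUBCLASS_LABEL[self.nag_subclass]}"

    @property
    def rank(self) -> int:
        return CLASS_ORDER.index(self.label) + 1


@dataclass
class ClassifiedSpacer:
    site: SpacerSite
    spacer_class: SpacerClass | None  # None when rejected
    ngg_hits: list[OffTargetHit] = field(default_factory=list)
    nag_hits: list[OffTargetHit] = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return self.spacer_class is None

    @property
    def label(self) -> str:
        return REJECTED if self.rejected else self.spacer_class.label


def ngg_group(ngg_hits: list[OffTargetHit]) -> str:
    """Group from NGG off-targets: A, B, or REJECTED.

    A: every NGG hit has >= 1 difference in the 10-nt seed (the conservative
    criterion).  B: every NGG hit has >= 1 difference in the 15-nt seed and
    >= 3 differences in total.  A spacer meeting A is labeled A even if it
    also meets B.  No NGG hits at all vacuously gives A.
    """
    if all(h.profile.seed10 >= 1 for h in ngg_hits):
        return GROUP_A
    if all(h.profile.seed15 >= 1 and h.profile.total >= 3 for h in ngg_hits):
        return GROUP_B
    return REJECTED


def nag_subclass(nag_hits: list[OffTargetHit]) -> float:
    """NAG off-target potential: 0 (none/seed-disrupted) to 2 (near-perfect).

    Mirrors the NGG A/B logic at NAG sites, then grades the remainder by the
    worst NAG site: subclass 1 if every NAG hit still has >= 2 differences,
    subclass 2 if some NAG site is within one difference of the spacer.
    """
    if all(h.profile.seed10 >= 1 for h in nag_hits):
        return 0
    if all(h.profile.seed15 >= 1 and h.profile.total >= 3 for h in nag_hits):
        return 0.1
    if all(h.profile.total >= 2 for h in nag_hits):
        return 1
    return 2


def classify_spacer(
    site: SpacerSite,
    ngg_hits: list[OffTargetHit],
    nag_hits: list[OffTargetHit],
) -> ClassifiedSpacer:
    """Combine the NGG group and NAG subclass into a class label or rejection."""
    group = ngg_group(ngg_hits)
    if group == REJECTED:
        return ClassifiedSpacer(site, None, ngg_hits, nag_hits)
    cls = SpacerClass(group=group, nag_subclass=nag_subclass(nag_hits))
    return ClassifiedSpacer(site, cls, ngg_hits, nag_hits)


def classify_genome(
    genome: Genome,
    params: SearchParams = SearchParams(pam_classes=frozenset({PAM_NGG, PAM_NAG})),
    spacer_len: int = 20,
) -> list[ClassifiedSpacer]:
    """Scan and classify every NGG spacer candidate in a genome.

    Candidate guides are NGG sites only; NAG sites enter the search purely as
    potential off-target loci.  Each candidate is searched against all sites
    (excluding its own locus), hits are split by PAM class, and the class is
    assigned.  A sequence occurring at several NGG loci sees its own copies
    as 0-difference off-targets and is rejected.
    """
    pam_classes = frozenset(params.pam_classes) | {PAM_NGG}
    search_params = SearchParams(
        max_mismatches=params.max_mismatches,
        max_gaps=params.max_gaps,
        mode=params.mode,
        word_size=params.word_size,
        pam_classes=pam_classes,
    )
    sites = scan_pam_sites(genome, pam_classes, spacer_len=spacer_len)
    searcher = OffTargetSearcher(genome, sites, search_params)
    out: list[ClassifiedSpacer] = []
    for site in sites:
        if site.pam_class != PAM_NGG:
            continue
        hits = searcher.search(site.protospacer, exclude_key=site.key())
        ngg_hits = [h for h in hits if h.site.pam_class == PAM_NGG]
        nag_hits = [h for h in hits if h.site.pam_class == PAM_NAG]
        out.append(classify_spacer(site, ngg_hits, nag_hits))
    return out


def compute_targetability(
    classified: list[ClassifiedSpacer],
    annotation: Annotation,
    admitted_ranks: set[int] = frozenset(range(1, 5)),
) -> float:
    """Fraction of transcription units containing an admitted spacer.

    A unit is targetable when its interval entirely contains the 20-nt
    protospacer interval of at least one admitted spacer, on either strand
    (the PAM may fall outside: the cut site lies within the protospacer).
    """
    if len(annotation) == 0:
        raise ValueError("annotation has no transcription units")
    admitted = [
        c.site.interval
        for c in classified
        if not c.rejected and c.spacer_class.rank in admitted_ranks
    ]
    covered = 0
    for _uid, unit in annotation.transcription_units:
        if any(unit.contains(iv) for iv in admitted):
            covered += 1
    return covered / len(annotation)
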