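"""Helix-loop-helix motif extraction, disulfide detection and scaffold curation.

The curation rule mirrors the screen used to assemble disulfide-rich
scaffold candidates: a chain passes when it is 10-50 residues long
(inclusive) and contains at least two cysteines.  Disulfide connectivity
is reported in the Roman-numeral convention of the cystine-rich peptide
field: cysteines are numbered I, II, ... by sequence position and bonded
pairs are listed sorted by first member (e.g. "I-IV, II-III" for the
alpha-hairpinin fold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .secstruct import SecStructAssignment
from .structure_io import Residue, Structure

__all__ = [
    "HelixLoopHelixMotif",
    "DisulfidePattern",
    "ScaffoldCandidate",
    "extract_hlh_motifs",
    "detect_disulfides",
    "scaffold_filter",
    "dedupe_candidates",
    "candidate_from_structure",
    "FILTER_MIN_LEN",
    "FILTER_MAX_LEN",
    "FILTER_MIN_CYS",
]

logger = logging.getLogger(__name__)

FILTER_MIN_LEN = 10
FILTER_MAX_LEN = 50
FILTER_MIN_CYS = 2

SG_SG_MAX = 2.3  # Angstrom; canonical S-S bond 2.05 plus slack
CB_CB_MAX = 4.5  # fallback when gamma sulfurs are missing
MAX_LOOP_LEN = 12

_ROMAN = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
          "XI", "XII", "XIII", "XIV", "XV", "XVI"]


@dataclass(frozen=True)
class HelixLoopHelixMotif:
    """Two helices joined by a loop; spans are 1-based inclusive label_id."""

    chain: str
    helix1: tuple[int, int]
    loop: tuple[int, int]
    helix2: tuple[int, int]
    source: str = ""

    def __post_init__(self) -> None:
        h1, lp, h2 = self.helix1, self.loop, self.helix2
        if not (h1[0] <= h1[1] < lp[0] <= lp[1] < h2[0] <= h2[1]):
            raise ValueError(f"spans must be ordered helix1 < loop < helix2: {h1},{lp},{h2}")
        if h1[1] - h1[0] + 1 < 4 or h2[1] - h2[0] + 1 < 4:
            raise ValueError("helices must be at least 4 residues")

    @property
    def helix1_ids(self) -> list[int]:
        return list(range(self.helix1[0], self.helix1[1] + 1))

    @property
    def loop_ids(self) -> list[int]:
        return list(range(self.loop[0], self.loop[1] + 1))

    @property
    def helix2_ids(self) -> list[int]:
        return list(range(self.helix2[0], self.helix2[1] + 1))


@dataclass(frozen=True)
class DisulfidePattern:
    """Bonded cysteine pairs indexed by sequence order (1-based)."""

    pairs: tuple[tuple[int, int], ...]

    @property
    def roman(self) -> str:
        return ", ".join(
            f"{_ROMAN[i - 1]}–{_ROMAN[j - 1]}" for i, j in sorted(self.pairs)
        )


@dataclass
class ScaffoldCandidate:
    source: str
    chain: str
    length: int
    n_cys: int
    sequence: str = ""
    motif: HelixLoopHelixMotif | None = None
    disulfides: DisulfidePattern = field(default_factory=lambda: DisulfidePattern(()))

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n_cys < 0:
            raise ValueError("n_cys must be >= 0")


def extract_hlh_motifs(
    s: Structure,
    chain: str,
    labels: SecStructAssignment,
    max_loop_len: int = MAX_LOOP_LEN,
) -> list[HelixLoopHelixMotif]:
    """Every consecutive pair of maximal helix runs separated by 1-12 residues.

    The gap residues form the loop; motifs are returned N->C.
    """
    if len(labels.labels) != len(s.chain(chain)):
        raise ValueError("labels length does not match chain length")
    runs = labels.helix_runs()
    motifs = []
    for (s1, e1), (s2, e2) in zip(runs, runs[1:]):
        gap = s2 - e1 - 1
        if 1 <= gap <= max_loop_len:
            motifs.append(
                HelixLoopHelixMotif(
                    chain=chain,
                    helix1=(s1, e1),
                    loop=(e1 + 1, s2 - 1),
                    helix2=(s2, e2),
                    source=s.id,
                )
            )
    return motifs


def _cys_anchor(res: Residue) -> tuple[str, np.ndarray] | None:
    """Preferred atom for disulfide geometry: SG, falling back to CB."""
    for name in ("SG", "CB"):
        a = res.atom(name)
        if a is not None:
            return name, a.position
    return None


def detect_disulfides(s: Structure, chain: str) -> DisulfidePattern:
    """Pair cysteines by gamma-sulfur proximity (greedy nearest-first).

    SG-SG <= 2.3 A marks a bond; when either SG is missing the CB-CB
    distance (<= 4.5 A) is used instead.  A cysteine within threshold of
    two partners after pairing triggers a warning and keeps the nearest.
    """
    cys = [r for r in s.chain(chain) if r.name == "CYS"]
    anchors = [(ordinal, _cys_anchor(res)) for ordinal, res in enumerate(cys, start=1)]

    candidates = []
    for ai in range(len(anchors)):
        for aj in range(ai + 1, len(anchors)):
            oi, anc_i = anchors[ai]
            oj, anc_j = anchors[aj]
            if anc_i is None or anc_j is None:
                continue
            dist = float(np.linalg.norm(anc_i[1] - anc_j[1]))
            threshold = SG_SG_MAX if (anc_i[0] == "SG" and anc_j[0] == "SG") else CB_CB_MAX
            if dist <= threshold:
                candidates.append((dist, oi, oj))

    candidates.sort()
    paired: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for dist, oi, oj in candidates:
        if oi in paired or oj in paired:
            logger.warning(
                "cysteine %s/%s within bonding distance (%.2f A) of an already "
                "paired partner; keeping nearest assignment", oi, oj, dist,
            )
            continue
        pairs.append((oi, oj))
        paired.update((oi, oj))
    return DisulfidePattern(tuple(sorted(pairs)))


def scaffold_filter(c: ScaffoldCandidate) -> tuple[bool, list[str]]:
    """Apply the curation rule; returns (pass, machine-readable reason codes)."""
    reasons = []
    if c.length < FILTER_MIN_LEN:
        reasons.append("too_short")
    if c.length > FILTER_MAX_LEN:
        reasons.append("too_long")
    if c.n_cys < FILTER_MIN_CYS:
        reasons.append("too_few_cys")
    return (not reasons, reasons)


def dedupe_candidates(cs: list[ScaffoldCandidate]) -> list[ScaffoldCandidate]:
    """One candidate per distinct chain sequence, ties to the smallest source id."""
    best: dict[str, ScaffoldCandidate] = {}
    for c in cs:
        key = c.sequence
        if key not in best or c.source < best[key].source:
            best[key] = c
    # preserve first-seen sequence order
    seen = set()
    out = []
    for c in cs:
        if c.sequence not in seen:
            seen.add(c.sequence)
            out.append(best[c.sequence])
    return out


def candidate_from_structure(
    s: Structure,
    chain: str,
    labels: SecStructAssignment | None = None,
) -> ScaffoldCandidate:
    """Build a ScaffoldCandidate (length, cysteine count, motif, disulfides)."""
    from .secstruct import assign_secstruct

    residues = s.chain(chain)
    seq = "".join(r.one_letter for r in residues)
    motif = None
    if labels is None and len(residues) >= 5:
        try:
            labels = assign_secstruct(s, chain)
        except ValueError:
            labels = None
    if labels is not None:
        motifs = extract_hlh_motifs(s, chain, labels)
        motif = motifs[0] if motifs else None
    return ScaffoldCandidate(
        source=s.id,
        chain=chain,
        length=len(residues),
        n_cys=seq.count("C"),
        sequence=seq,
        motif=motif,
        disulfides=detect_disulfides(s, chain),
    )
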