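"""C-alpha based secondary-structure assignment.

Many peptide NMR and older X-ray entries lack complete backbones, so the
assignment here uses only C-alpha geometry, in the spirit of P-SEA:
short-range CA(i)-CA(i+k) distances discriminate helix from extended
chain.  A residue is called helical when enough of the 5-residue windows
covering it satisfy the helix distance criteria, which smooths over
single-residue dropouts; helix runs shorter than 4 residues are demoted
to coil because they cannot anchor a framework alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Structure

__all__ = ["SecStructParams", "SecStructAssignment", "assign_secstruct"]


@dataclass(frozen=True)
class SecStructParams:
    """Distance windows (Angstrom) for the CA-only assignment."""

    helix_d2: tuple[float, float] = (5.0, 6.0)   # d(i, i+2)
    helix_d3: tuple[float, float] = (4.8, 5.8)   # d(i, i+3)
    helix_d4: tuple[float, float] = (5.8, 7.0)   # d(i, i+4)
    strand_d2: tuple[float, float] = (6.6, 7.4)  # d(i, i+2), near-straight
    strand_min_angle: float = 120.0              # CA pseudo-bond angle, degrees
    min_helix_len: int = 4
    window_votes: int = 3  # of the 5 windows covering a residue


@dataclass
class SecStructAssignment:
    labels: str
    parameters: SecStructParams = field(default_factory=SecStructParams)

    def __post_init__(self) -> None:
        if set(self.labels) - set("HEC"):
            raise ValueError("labels must be over {H, E, C}")

    def helix_runs(self) -> list[tuple[int, int]]:
        """Maximal H runs as 1-based inclusive (start, end) label_id spans."""
        runs: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels, start=1):
            if lab == "H" and start is None:
                start = i
            elif lab != "H" and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(self.labels)))
        return runs


def _in(window: tuple[float, float], value: float) -> bool:
    return window[0] <= value <= window[1]


def assign_secstruct(
    s: Structure, chain: str, params: SecStructParams | None = None
) -> SecStructAssignment:
    """Assign H/E/C per residue of a chain from CA geometry alone.

    Requires at least 5 residues with CA.  The result depends only on
    pairwise CA distances and pseudo-bond angles, so it is invariant
    under rigid transforms of the coordinates.
    """
    p = params or SecStructParams()
    coords = s.ca_coords(chain)
    n = len(coords)
    if n < 5:
        raise ValueError(f"chain {chain!r}: need >=5 residues with CA, got {n}")

    def d(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    # helix window j covers residues j..j+4
    helix_win = np.zeros(n, dtype=bool)
    for j in range(n - 4):
        helix_win[j] = (
            _in(p.helix_d2, d(j, j + 2))
            and _in(p.helix_d3, d(j, j + 3))
            and _in(p.helix_d4, d(j, j + 4))
        )

    # pseudo-bond angle at residue k (between CA(k-1)->CA(k) and CA(k)->CA(k+1))
    def angle(k: int) -> float:
        u = coords[k] - coords[k - 1]
        v = coords[k + 1] - coords[k]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(-c, -1.0, 1.0))))

    strand_win = np.zeros(n, dtype=bool)
    for j in range(n - 2):
        strand_win[j] = _in(p.strand_d2, d(j, j + 2)) and angle(j + 1) >= p.strand_min_angle

    # core helix call: enough of the windows covering a residue satisfy the
    # helix distances (near chain ends fewer than 5 windows exist; require
    # all of them)
    is_helix = np.zeros(n, dtype=bool)
    for i in range(n):
        lo, hi = max(0, i - 4), min(i, n - 5)
        if hi < lo:
            continue
        votes = int(helix_win[lo : hi + 1].sum())
        covering = hi - lo + 1
        if votes >= min(p.window_votes, covering):
            is_helix[i] = True

    # extension: a satisfied window that touches a core run claims all five
    # of its residues — recovers the two junction residues the vote erodes
    # at helix ends without promoting isolated spurious windows
    for j in range(n - 4):
        if helix_win[j] and is_helix[j : j + 5].any():
            is_helix[j : j + 5] = True

    # terminal refinement: a residue flanking a helix run is promoted when
    # at least 2 of its 3 individual helix distances into the run hold —
    # a run-boundary residue is otherwise supported by a single window,
    # which one noisy distance can veto
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if is_helix[i]:
                continue
            if i + 1 < n and is_helix[i + 1]:
                checks = [(p.helix_d2, i, i + 2), (p.helix_d3, i, i + 3),
                          (p.helix_d4, i, i + 4)]
            elif i - 1 >= 0 and is_helix[i - 1]:
                checks = [(p.helix_d2, i - 2, i), (p.helix_d3, i - 3, i),
                          (p.helix_d4, i - 4, i)]
            else:
                continue
            valid = [(w, a, b) for w, a, b in checks if a >= 0 and b < n]
            if len(valid) >= 2 and sum(_in(w, d(a, b)) for w, a, b in valid) >= 2:
                is_helix[i] = True
                changed = True

    labels = []
    for i in range(n):
        if is_helix[i]:
            labels.append("H")
            continue
        slo, shi = max(0, i - 2), min(i, n - 3)
        svotes = int(strand_win[slo : shi + 1].sum()) if shi >= slo else 0
        labels.append("E" if svotes >= 1 else "C")

    # demote helix runs shorter than the minimum length
    lab = "".join(labels)
    out = list(lab)
    i = 0
    while i < n:
        if out[i] == "H":
            j = i
            while j < n and out[j] == "H":
                j += 1
            if j - i < p.min_helix_len:
                out[i:j] = ["C"] * (j - i)
            i = j
        else:
            i += 1
    return SecStructAssignment(labels="".join(out), parameters=p)
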