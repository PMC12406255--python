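"""Seeded generators for every fixture the analysis surface consumes.

The geometric generators build helix-loop-helix (HLH) peptide backbones
from canonical alpha-helix parameters (1.5 A rise, 100 degrees twist per
residue, 2.3 A radius) joined by a circular-arc loop with C-alpha
spacing near 3.8 A, optionally decorated with disulfide staples
(gamma sulfurs planted at bonding distance), Gaussian coordinate noise
and a seeded rigid transform.  They return the ground truth alongside
the structure, so every downstream module has a closed-loop test:
generate -> analyze -> recover the planted answer.

The statistical generators draw concentration-response data from the
constrained three-parameter inhibition model, serum-decay series from
the one-phase decay model, and residue alignments with controlled
per-column conservation.  All generators are pure functions of
(parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .structure_io import AtomRecord, Residue, Structure, write_structure
from .motif import FILTER_MAX_LEN, FILTER_MIN_CYS, FILTER_MIN_LEN

__all__ = [
    "HelixParams",
    "FixtureRecipe",
    "HLHTruth",
    "build_helix_coords",
    "build_hlh",
    "build_library",
    "simulate_dose_response",
    "simulate_decay",
    "simulate_alignment",
]

CA_SPACING = 3.8  # A, consecutive C-alpha distance along the loop
SS_BOND_LEN = 2.05  # A, planted SG-SG distance
HAIRPIN_SEPARATION = 10.0  # A, default axis-to-axis helix distance

# default assay designs emulated by the statistical generators: an
# 8-point 10-fold-bracketed dilution series read in quadruplicate
# (migration concentration-response experiments run 4 independent
# measurements) and the front-loaded doubling schedule standard for
# serum-stability sampling
DEFAULT_DOSE_CONCENTRATIONS = np.logspace(-1, 3, 8)  # nM
DEFAULT_DOSE_REPS = 4
DEFAULT_DECAY_TIMES = np.array([0.0, 1, 2, 4, 8, 16, 24, 48])  # h


@dataclass(frozen=True)
class HelixParams:
    n_res: int
    rise: float = 1.5  # A per residue
    twist: float = 100.0  # degrees per residue
    radius: float = 2.3  # A

    def __post_init__(self) -> None:
        if self.n_res < 4:
            raise ValueError("helix needs >= 4 residues")
        if self.rise <= 0 or self.radius <= 0:
            raise ValueError("rise and radius must be positive")


@dataclass(frozen=True)
class FixtureRecipe:
    helix1: HelixParams
    loop_len: int
    helix2: HelixParams
    cys_positions: tuple[int, ...] = ()  # 1-based sequence positions
    disulfide_pairs: tuple[tuple[int, int], ...] = ()  # 1-based cysteine ordinals
    noise_sigma: float = 0.0
    transform_seed: int | None = None

    def __post_init__(self) -> None:
        n = self.helix1.n_res + self.loop_len + self.helix2.n_res
        for p in self.cys_positions:
            if not 1 <= p <= n:
                raise ValueError(f"cys position {p} outside sequence 1..{n}")
        for i, j in self.disulfide_pairs:
            if not (1 <= i < j <= len(self.cys_positions)):
                raise ValueError(f"disulfide pair ({i},{j}) must index cys ordinals")

    @property
    def n_res(self) -> int:
        return self.helix1.n_res + self.loop_len + self.helix2.n_res


@dataclass
class HLHTruth:
    labels: str  # planted H/C labels
    helix1: tuple[int, int]
    loop: tuple[int, int]
    helix2: tuple[int, int]
    disulfide_pairs: tuple[tuple[int, int], ...]
    seed: int | None = None


def build_helix_coords(p: HelixParams, phase: float = 0.0) -> np.ndarray:
    """Canonical alpha-helix C-alpha trace along +z."""
    i = np.arange(p.n_res)
    theta = np.radians(p.twist) * i + phase
    return np.column_stack(
        [p.radius * np.cos(theta), p.radius * np.sin(theta), p.rise * i]
    )


def _arc_points(a: np.ndarray, b: np.ndarray, n_interior: int,
                bulge_dir: np.ndarray, spacing: float = CA_SPACING) -> np.ndarray:
    """Interior points of a circular arc from a to b with given path length.

    The arc lies in the plane of the chord and ``bulge_dir`` and has
    total length spacing * (n_interior + 1).
    """
    chord = float(np.linalg.norm(b - a))
    target_len = spacing * (n_interior + 1)
    if chord > target_len + 1e-9:
        raise ValueError("endpoints too far apart for the requested loop length")
    u = (b - a) / chord
    w = bulge_dir - np.dot(bulge_dir, u) * u
    if np.linalg.norm(w) < 1e-9:
        raise ValueError("bulge direction parallel to chord")
    w = w / np.linalg.norm(w)

    if target_len - chord < 1e-9:  # essentially straight
        ts = np.linspace(0, 1, n_interior + 2)[1:-1]
        return a + np.outer(ts, b - a)

    # solve arc half-angle: chord = 2 R sin(phi), length = 2 R phi
    f = lambda phi: math.sin(phi) / phi - chord / target_len
    phi = brentq(f, 1e-9, math.pi - 1e-9)
    R = target_len / (2 * phi)
    mid = (a + b) / 2
    center = mid - w * R * math.cos(phi)
    # sample angles from a to b around the center in the (u, w) plane
    va = a - center
    angles = np.linspace(-phi, phi, n_interior + 2)[1:-1]
    sag = R * math.cos(phi)
    pts = []
    for ang in angles:
        along = R * math.sin(ang)
        out = R * math.cos(ang)
        pts.append(mid + u * along + w * (out - sag))
    return np.array(pts)


def build_hlh(recipe: FixtureRecipe) -> tuple[Structure, HLHTruth]:
    """Build an HLH C-alpha (plus Cys SG) structure with ground truth.

    Helix 1 runs along +z; helix 2 runs antiparallel at a hairpin
    separation chosen to keep the loop arc C-alpha spacing near 3.8 A.
    Gaussian noise (``noise_sigma``) and a seeded rigid transform are
    applied to C-alpha positions; gamma sulfurs for planted disulfides
    are placed afterwards so the staple geometry is exact by
    construction.
    """
    n1, nl, n2 = recipe.helix1.n_res, recipe.loop_len, recipe.helix2.n_res
    h1 = build_helix_coords(recipe.helix1)

    # antiparallel second helix, offset in +x; pulled in along the loop
    # chord when the requested loop is too short to bridge the default
    # hairpin separation
    h2_local = build_helix_coords(recipe.helix2)
    h2 = h2_local.copy()
    h2[:, 2] = -h2[:, 2]  # run along -z, back beside helix 1
    h2 += np.array([HAIRPIN_SEPARATION, 0.0, h1[-1, 2]])
    max_chord = CA_SPACING * (nl + 1) * 0.9
    chord0 = float(np.linalg.norm(h2[0] - h1[-1]))
    if chord0 > max_chord:
        if max_chord < 4.5:
            raise ValueError(
                f"loop of {nl} residues cannot bridge two helices without clashing"
            )
        h2 += (h1[-1] - h2[0]) * (1.0 - max_chord / chord0)

    loop = _arc_points(h1[-1], h2[0], nl, bulge_dir=np.array([0.3, 0.2, 1.0]))
    coords = np.vstack([h1, loop, h2])

    rng = np.random.default_rng(recipe.transform_seed)
    if recipe.noise_sigma > 0:
        coords = coords + rng.normal(0.0, recipe.noise_sigma, coords.shape)
    if recipe.transform_seed is not None:
        R = Rotation.random(random_state=rng).as_matrix()
        t = rng.uniform(-20, 20, 3)
        coords = coords @ R.T + t

    # place SG atoms for planted disulfides on the (possibly transformed) CAs
    sg: dict[int, np.ndarray] = {}
    cys_set = set(recipe.cys_positions)
    for oi, oj in recipe.disulfide_pairs:
        pi, pj = recipe.cys_positions[oi - 1], recipe.cys_positions[oj - 1]
        ca_i, ca_j = coords[pi - 1], coords[pj - 1]
        u = ca_j - ca_i
        dist = np.linalg.norm(u)
        u = u / dist
        gap = (dist - SS_BOND_LEN) / 2
        sg[pi] = ca_i + u * gap
        sg[pj] = ca_j - u * gap
    for p in cys_set - set(sg):
        sg[p] = coords[p - 1] + np.array([0.0, 0.0, 2.4])

    residues = []
    for idx in range(recipe.n_res):
        pos = idx + 1
        name = "CYS" if pos in cys_set else "ALA"
        atoms = [AtomRecord(name="CA", element="C", position=coords[idx])]
        if pos in sg:
            atoms.append(AtomRecord(name="SG", element="S", position=sg[pos]))
        residues.append(Residue(name=name, seq_id=pos, label_id=pos, atoms=atoms))
    s = Structure(id="SYNTH", chains={"A": residues})

    truth = HLHTruth(
        labels="H" * n1 + "C" * nl + "H" * n2,
        helix1=(1, n1),
        loop=(n1 + 1, n1 + nl),
        helix2=(n1 + nl + 1, recipe.n_res),
        disulfide_pairs=recipe.disulfide_pairs,
        seed=recipe.transform_seed,
    )
    return s, truth


def build_library(
    out_dir: str | Path,
    n: int = 20,
    seed: int = 0,
    lengths: list[int] | None = None,
    cys_counts: list[int] | None = None,
    noise_sigma: float = 0.1,
) -> pd.DataFrame:
    """Write a deterministic scaffold library of PDB files plus a truth table.

    Entry attributes (total length, cysteine count) cycle through the
    provided grids; by default the grid covers both curation boundaries
    (lengths 9, 10, 50, 51) and cysteine counts 0-4.  The returned truth
    table states, per entry, the length, cysteine count and the expected
    curation verdict (10 <= length <= 50 and >= 2 Cys).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # default grid covers both curation length boundaries at >=2 Cys plus
    # cysteine-poor entries, so the length and cysteine rules are each
    # exercised independently
    default_grid = [(9, 2), (10, 2), (50, 2), (51, 2), (14, 0),
                    (20, 4), (27, 4), (33, 1), (41, 2), (48, 3)]
    if lengths is None and cys_counts is None:
        grid = default_grid
    else:
        lengths = lengths or [p[0] for p in default_grid]
        cys_counts = cys_counts or [p[1] for p in default_grid]
        grid = [(lengths[i % len(lengths)], cys_counts[i % len(cys_counts)])
                for i in range(n)]
    rng = np.random.default_rng(seed)
    rows = []
    for idx in range(n):
        total, want_cys = grid[idx % len(grid)]
        n_cys = min(want_cys, total // 2)
        # split total into helix/loop/helix with helices >= 4
        loop_len = max(1, min(5, total - 8))
        n1 = max(4, (total - loop_len) // 2)
        n2 = total - loop_len - n1
        if n2 < 4:  # very short chains: shrink the loop instead
            loop_len = total - 8
            n1 = n2 = 4
        if loop_len < 1:
            raise ValueError(f"length {total} too short for an HLH fixture")
        # spread cysteines over helix1 and helix2 symmetrically
        cys_positions = []
        for k in range(n_cys):
            if k % 2 == 0:
                cys_positions.append(1 + (k // 2) * 2)
            else:
                cys_positions.append(total - (k // 2) * 2)
        cys_positions = tuple(sorted(set(cys_positions)))
        # staple paired cysteines with nested (hairpinin-style) connectivity
        n_pairable = len(cys_positions) - len(cys_positions) % 2
        pairs = tuple((k + 1, n_pairable - k) for k in range(n_pairable // 2))
        recipe = FixtureRecipe(
            helix1=HelixParams(n_res=n1),
            loop_len=loop_len,
            helix2=HelixParams(n_res=n2),
            cys_positions=cys_positions,
            disulfide_pairs=pairs,
            noise_sigma=noise_sigma,
            transform_seed=int(rng.integers(0, 2**31 - 1)),
        )
        s, _truth = build_hlh(recipe)
        entry_id = f"SYN{idx:03d}"
        s.id = entry_id
        path = out_dir / f"{entry_id.lower()}.pdb"
        write_structure(s, path)
        expected = (FILTER_MIN_LEN <= total <= FILTER_MAX_LEN
                    and len(cys_positions) >= FILTER_MIN_CYS)
        rows.append(
            {
                "source": entry_id,
                "path": str(path),
                "length": total,
                "n_cys": len(cys_positions),
                "noise_sigma": noise_sigma,
                "expected_pass": expected,
            }
        )
    truth = pd.DataFrame(rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return truth


def simulate_dose_response(
    ec50: float,
    bottom: float,
    concentrations: np.ndarray,
    sigma: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Responses from the constrained inhibition model plus Gaussian noise.

    Y = bottom + (100 - bottom)/(1 + c/ec50); columns: concentration,
    replicate, response (% of untreated control).
    """
    if ec50 <= 0:
        raise ValueError("ec50 must be positive")
    c = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    clean = bottom + (100.0 - bottom) / (1.0 + c / ec50)
    rows = []
    for rep in range(n_reps):
        noisy = clean + rng.normal(0.0, sigma, c.shape)
        for ci, yi in zip(c, noisy):
            rows.append({"concentration": ci, "replicate": rep, "response": yi})
    return pd.DataFrame(rows)


def simulate_decay(
    half_life: float,
    times: np.ndarray,
    plateau: float = 0.0,
    sigma: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """One-phase decay series, % remaining vs time (t = 0 pinned at 100)."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    t = np.asarray(times, dtype=float)
    rng = np.random.default_rng(seed)
    k = math.log(2) / half_life
    clean = (100.0 - plateau) * np.exp(-k * t) + plateau
    noisy = clean + rng.normal(0.0, sigma, t.shape)
    noisy[t == 0] = 100.0
    return pd.DataFrame({"time_h": t, "remaining_pct": noisy})


def simulate_alignment(
    n_seqs: int,
    column_profiles: list[dict[str, float]],
    seed: int = 0,
) -> list[str]:
    """Draw an alignment with i.i.d. per-column residue distributions.

    ``column_profiles`` gives one dict per column mapping residue (or
    '-') to probability; probabilities are renormalized.  A uniform
    distribution over the 20 residues can be requested with an empty
    dict.
    """
    from .conservation import AA20

    if n_seqs < 1:
        raise ValueError("need at least one sequence")
    rng = np.random.default_rng(seed)
    cols = []
    for prof in column_profiles:
        if not prof:
            letters = list(AA20)
            probs = np.full(20, 1 / 20)
        else:
            letters = list(prof)
            probs = np.array([prof[l] for l in letters], dtype=float)
            probs = probs / probs.sum()
        cols.append(rng.choice(letters, size=n_seqs, p=probs))
    return ["".join(col[i] for col in cols) for i in range(n_seqs)]
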