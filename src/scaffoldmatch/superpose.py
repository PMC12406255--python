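"""Rigid-body superposition and conformational scaffold ranking.

Three alignment modes share one currency, the C-alpha RMSD after an
optimal rigid transform:

* :func:`kabsch` — least-squares superposition of pre-paired point sets
  via SVD, with the determinant sign correction that guarantees a proper
  rotation.
* :func:`framework_align` — the scaffold-matching score: the
  correspondence is built from helix residues only (helix1 onto helix1,
  helix2 onto helix2, sliding the shorter helix along the longer and
  jointly choosing the offset pair that minimizes RMSD), leaving the loop
  free.  When loop lengths match, the post-transform loop RMSD is
  reported separately.
* :func:`ce_style_align` — a sequence-independent, combinatorial-
  extension-style alignment over 8-residue fragment pairs whose internal
  distance matrices agree, for whole-chain comparisons.

All modes use C-alpha coordinates only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motif import HelixLoopHelixMotif
from .structure_io import Structure

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "framework_align",
    "ce_style_align",
    "rank_candidates",
]

logger = logging.getLogger(__name__)

CE_FRAGMENT_LEN = 8
CE_DISTANCE_THRESHOLD = 3.0  # Angstrom, mean |d_P - d_Q| over a fragment pair


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3 proper orthogonal
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float
    correspondence: list[tuple[int, int]] = field(default_factory=list)
    mode: str = "all_atom_ca"
    loop_rmsd: float | None = None
    ill_conditioned: bool = False
    aligned_length: int = 0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Map candidate-frame coordinates into the query frame."""
        return coords @ self.rotation.T + self.translation


def kabsch(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition of Q onto P (paired rows).

    Returns the rotation/translation minimizing sum |P_i - (R Q_i + t)|^2
    and the resulting RMSD.  Collinear (rank-deficient) inputs are solved
    but flagged ``ill_conditioned`` since the rotation about the line is
    arbitrary.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"P and Q must be matching n x 3 arrays, got {P.shape}, {Q.shape}")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")

    cP = P.mean(axis=0)
    cQ = Q.mean(axis=0)
    H = (Q - cQ).T @ (P - cP)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cP - R @ cQ
    diff = P - (Q @ R.T + t)
    rmsd = float(np.sqrt((diff**2).sum() / n))
    # rank deficiency: the two smallest singular values comparable to zero
    ill = bool(S[1] < 1e-8 * max(S[0], 1.0))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd, mode="all_atom_ca",
        ill_conditioned=ill, aligned_length=n,
    )


def _helix_windows(q_ids: list[int], c_ids: list[int]) -> list[tuple[list[int], list[int]]]:
    """All equal-length window pairings obtained by sliding the shorter helix."""
    L = min(len(q_ids), len(c_ids))
    out = []
    for qo in range(len(q_ids) - L + 1):
        for co in range(len(c_ids) - L + 1):
            out.append((q_ids[qo : qo + L], c_ids[co : co + L]))
    return out


def framework_align(
    query: HelixLoopHelixMotif,
    query_structure: Structure,
    cand: HelixLoopHelixMotif,
    cand_structure: Structure,
) -> SuperpositionResult:
    """Helix-framework-constrained superposition of two HLH motifs.

    Only helix residues enter the fit; the offsets of both helix windows
    are optimized jointly and exhaustively (offset ranges are tiny for
    peptide-scale helices).  Loop residues are excluded from fitting but,
    when the loop lengths match, their post-transform RMSD is reported in
    ``loop_rmsd``.
    """
    h1_pairs = _helix_windows(query.helix1_ids, cand.helix1_ids)
    h2_pairs = _helix_windows(query.helix2_ids, cand.helix2_ids)

    qcoords = {i: c for i, c in zip(
        sorted(set(query.helix1_ids + query.loop_ids + query.helix2_ids)),
        query_structure.ca_coords(query.chain, sorted(set(
            query.helix1_ids + query.loop_ids + query.helix2_ids))))}
    ccoords = {i: c for i, c in zip(
        sorted(set(cand.helix1_ids + cand.loop_ids + cand.helix2_ids)),
        cand_structure.ca_coords(cand.chain, sorted(set(
            cand.helix1_ids + cand.loop_ids + cand.helix2_ids))))}

    best: SuperpositionResult | None = None
    for q1, c1 in h1_pairs:
        for q2, c2 in h2_pairs:
            q_ids = q1 + q2
            c_ids = c1 + c2
            P = np.array([qcoords[i] for i in q_ids])
            Q = np.array([ccoords[i] for i in c_ids])
            res = kabsch(P, Q)
            if best is None or res.rmsd < best.rmsd:
                res.correspondence = list(zip(q_ids, c_ids))
                res.mode = "framework"
                best = res
    assert best is not None  # helices >=4 guarantee at least one window pair

    if len(query.loop_ids) == len(cand.loop_ids):
        Ploop = np.array([qcoords[i] for i in query.loop_ids])
        Qloop = best.apply(np.array([ccoords[i] for i in cand.loop_ids]))
        best.loop_rmsd = float(np.sqrt(((Ploop - Qloop) ** 2).sum() / len(Ploop)))
    return best


def _fragment_distance_score(P: np.ndarray, Q: np.ndarray) -> float:
    """Mean absolute difference of the two fragments' internal CA distances."""
    dP = np.linalg.norm(P[:, None] - P[None, :], axis=-1)
    dQ = np.linalg.norm(Q[:, None] - Q[None, :], axis=-1)
    iu = np.triu_indices(len(P), k=1)
    return float(np.abs(dP[iu] - dQ[iu]).mean())


def ce_style_align(
    P: np.ndarray,
    Q: np.ndarray,
    fragment_len: int = CE_FRAGMENT_LEN,
    threshold: float = CE_DISTANCE_THRESHOLD,
) -> SuperpositionResult | None:
    """Sequence-independent alignment over similar 8-residue fragment pairs.

    Admissible fragment pairs (distance-matrix score below ``threshold``)
    are chained into the longest mutually consistent N->C path by dynamic
    programming; the final transform and RMSD come from a Kabsch fit over
    all residues on the path.  Returns None when no admissible fragment
    pair exists.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    m, n = len(P), len(Q)
    if m < fragment_len or n < fragment_len:
        raise ValueError(f"both chains need >= {fragment_len} residues")

    afps = []  # (i, j, score)
    for i in range(m - fragment_len + 1):
        for j in range(n - fragment_len + 1):
            score = _fragment_distance_score(
                P[i : i + fragment_len], Q[j : j + fragment_len]
            )
            if score <= threshold:
                afps.append((i, j, score))
    if not afps:
        return None

    # DP over AFPs ordered by (i, j): maximize chained fragment count.
    # Distance-matrix similarity alone cannot distinguish register shifts
    # on self-similar (helical) chains, so chain admissibility combines a
    # cheap inter-fragment distance check with rigid compatibility: the
    # Kabsch RMSD over the union of the two fragments must stay below the
    # threshold, and ties prefer the most rigidly consistent predecessor.
    afps.sort()
    k = len(afps)
    best_len = [1] * k
    prev = [-1] * k

    def union_rmsd(a: int, b: int) -> float:
        ia, ja, _ = afps[a]
        ib, jb, _ = afps[b]
        idx_p = list(range(ia, ia + fragment_len)) + list(range(ib, ib + fragment_len))
        idx_q = list(range(ja, ja + fragment_len)) + list(range(jb, jb + fragment_len))
        return kabsch(P[idx_p], Q[idx_q]).rmsd

    for b in range(k):
        ib, jb, _ = afps[b]
        best_prev = None  # (length, union rmsd, index)
        for a in range(b):
            ia, ja, _ = afps[a]
            if ib < ia + fragment_len or jb < ja + fragment_len:
                continue
            if abs(np.linalg.norm(P[ia] - P[ib]) -
                   np.linalg.norm(Q[ja] - Q[jb])) > threshold:
                continue
            cand_len = best_len[a] + 1
            if best_prev is not None and cand_len < best_prev[0]:
                continue
            u = union_rmsd(a, b)
            if u > threshold:
                continue
            if best_prev is None or (cand_len, -u) > (best_prev[0], -best_prev[1]):
                best_prev = (cand_len, u, a)
        if best_prev is not None:
            best_len[b] = best_prev[0]
            prev[b] = best_prev[2]

    def path_result(end: int) -> SuperpositionResult:
        path = []
        b = end
        while b >= 0:
            path.append(afps[b])
            b = prev[b]
        path.reverse()
        pairs = []
        for i, j, _ in path:
            pairs.extend((i + off, j + off) for off in range(fragment_len))
        res = kabsch(P[[i for i, _ in pairs]], Q[[j for _, j in pairs]])
        res.mode = "ce_style"
        res.correspondence = [(i + 1, j + 1) for i, j in pairs]  # 1-based
        res.aligned_length = len(pairs)
        return res

    # among maximal-length paths, keep the one with the lowest fitted RMSD
    max_len = max(best_len)
    best = None
    for b in range(k):
        if best_len[b] == max_len:
            res = path_result(b)
            if best is None or res.rmsd < best.rmsd:
                best = res
    return best


def rank_candidates(
    query: HelixLoopHelixMotif,
    query_structure: Structure,
    library: list[tuple[HelixLoopHelixMotif | None, Structure]],
    mode: str = "framework",
) -> pd.DataFrame:
    """Score every candidate motif against the query and rank by RMSD.

    Rows are sorted ascending by RMSD, ties by aligned length (longer
    first) then source id.  Candidates without a motif are skipped with a
    logged reason.
    """
    rows = []
    for cand_motif, cand_structure in library:
        if cand_motif is None:
            logger.info("skipping %s: no helix-loop-helix motif", cand_structure.id)
            continue
        if mode == "framework":
            res = framework_align(query, query_structure, cand_motif, cand_structure)
        elif mode == "ce_style":
            res = ce_style_align(
                query_structure.ca_coords(query.chain),
                cand_structure.ca_coords(cand_motif.chain),
            )
            if res is None:
                logger.info("skipping %s: no admissible CE fragment pair",
                            cand_structure.id)
                continue
        else:
            raise ValueError(f"unknown mode {mode!r}")
        rows.append(
            {
                "source": cand_structure.id,
                "chain": cand_motif.chain,
                "mode": res.mode,
                "rmsd": res.rmsd,
                "aligned_length": len(res.correspondence),
                "loop_rmsd": res.loop_rmsd,
            }
        )
    df = pd.DataFrame(
        rows, columns=["source", "chain", "mode", "rmsd", "aligned_length", "loop_rmsd"]
    )
    if len(df):
        df = df.sort_values(
            by=["rmsd", "aligned_length", "source"],
            ascending=[True, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df
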