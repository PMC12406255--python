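"""Per-column conservation profiling of pre-aligned homolog sets.

For each alignment column the profile reports residue frequencies (gap
counted separately), Shannon entropy over the 20 amino acids, the
information content IC = log2(20) - entropy in bits, and the consensus
residue.  This is the computation behind an amino-acid sequence logo:
letter heights are frequency x IC.  Entropy excludes gaps by default; a
gap-fraction column is reported alongside.  An optional small-sample
correction (the WebLogo convention, e_n = 19 / (2 ln2 n)) can be
subtracted from IC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ConservationProfile", "conservation_profile", "export_logo_matrix",
           "AA20", "MAX_IC_BITS"]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MAX_IC_BITS = math.log2(20)


@dataclass
class ConservationProfile:
    n_sequences: int
    frequencies: pd.DataFrame  # index = 1-based position, columns = AA20 + '-'
    entropy: np.ndarray  # bits, per column, gaps excluded
    information: np.ndarray  # bits, log2(20) - entropy, clipped at 0
    consensus: str  # per column; '-' for all-gap columns
    gap_fraction: np.ndarray

    def __len__(self) -> int:
        return len(self.frequencies)


def conservation_profile(
    alignment: list[str],
    small_sample_correction: bool = False,
) -> ConservationProfile:
    """Column-wise conservation of an equal-length, gapped alignment.

    Frequencies per column (over 20 residues + gap) sum to 1; entropy and
    IC are computed over the residue distribution renormalized without
    gaps.  Consensus ties resolve alphabetically.
    """
    if not alignment:
        raise ValueError("alignment must contain at least one sequence")
    length = len(alignment[0])
    if any(len(s) != length for s in alignment):
        raise ValueError("ragged alignment: all sequences must have equal length")
    alphabet = AA20 + GAP
    for s in alignment:
        bad = set(s.upper()) - set(alphabet)
        if bad:
            raise ValueError(f"invalid alignment character(s): {''.join(sorted(bad))}")

    n = len(alignment)
    arr = np.array([list(s.upper()) for s in alignment])
    counts = np.zeros((length, 21), dtype=float)
    for k, ch in enumerate(alphabet):
        counts[:, k] = (arr == ch).sum(axis=0)
    freqs = counts / n

    aa_counts = counts[:, :20]
    non_gap = aa_counts.sum(axis=1)
    entropy = np.zeros(length)
    information = np.zeros(length)
    consensus = []
    for i in range(length):
        if non_gap[i] == 0:
            consensus.append(GAP)
            continue
        pvec = aa_counts[i] / non_gap[i]
        nz = pvec[pvec > 0]
        entropy[i] = float(-(nz * np.log2(nz)).sum())
        ic = MAX_IC_BITS - entropy[i]
        if small_sample_correction:
            ic -= (20 - 1) / (2 * math.log(2) * non_gap[i])
        information[i] = max(ic, 0.0)
        best = pvec.max()
        consensus.append(next(AA20[k] for k in range(20) if pvec[k] == best))

    return ConservationProfile(
        n_sequences=n,
        frequencies=pd.DataFrame(
            freqs, index=range(1, length + 1), columns=list(alphabet)
        ),
        entropy=entropy,
        information=information,
        consensus="".join(consensus),
        gap_fraction=freqs[:, 20].copy(),
    )


def export_logo_matrix(
    p: ConservationProfile, path: str | Path, heights: str = "bits"
) -> pd.DataFrame:
    """Write the logo height matrix as TSV (rows = positions, columns = residues).

    ``heights='bits'`` scales non-gap residue frequencies by the column
    IC (classic information logo); ``heights='frequency'`` exports raw
    non-gap-renormalized frequencies.  All-gap columns export zeros.
    The written frame is also returned.
    """
    if heights not in ("bits", "frequency"):
        raise ValueError("heights must be 'bits' or 'frequency'")
    freqs = p.frequencies[list(AA20)].to_numpy()
    non_gap = freqs.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(non_gap[:, None] > 0, freqs / non_gap[:, None], 0.0)
    mat = rel * p.information[:, None] if heights == "bits" else rel
    df = pd.DataFrame(mat, index=p.frequencies.index, columns=list(AA20))
    df.index.name = "position"
    df.to_csv(path, sep="\t", float_format="%.9g")
    return df
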