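"""Masses of modified peptides.

Neutral monoisotopic and average masses are computed from elemental
composition (pyteomics residue compositions) with the standard
peptide-chemistry bookkeeping:

* N-terminal acetylation adds C2H2O (+42.01057 Da mono),
* C-terminal amidation replaces the terminal OH with NH2 (-0.98402 Da),
* each disulfide bond removes H2 (-2.01565 Da),
* norleucine (Z) contributes the C6H11NO residue composition, identical
  to leucine/isoleucine.

[M+H]+ adds one proton (1.00728 Da).  The [M+H]+ values printed for
synthesized peptide series in the literature usually follow the
monoisotopic convention, which is what the ``mono_mh`` field reports.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

from .graft import PeptideSpec

__all__ = ["MassResult", "compute_mass", "mass_delta", "PROTON_MASS"]

PROTON_MASS = 1.00727646688

_ACETYL = _pmass.Composition(formula="C2H2O")
_AMIDE_DELTA = _pmass.Composition(formula="N1H1") - _pmass.Composition(formula="O1")
_H2 = _pmass.Composition(formula="H2")
_WATER = _pmass.Composition(formula="H2O")

# residue compositions: standard 20 plus Z (norleucine, C6H11NO)
_AA_COMP = dict(_pmass.std_aa_comp)
_AA_COMP["Z"] = _pmass.Composition(formula="C6H11NO")


@dataclass(frozen=True)
class MassResult:
    mono_neutral: float
    avg_neutral: float
    composition_delta: dict[str, float]

    @property
    def mono_mh(self) -> float:
        return self.mono_neutral + PROTON_MASS

    @property
    def avg_mh(self) -> float:
        return self.avg_neutral + PROTON_MASS


def _composition(p: PeptideSpec) -> _pmass.Composition:
    comp = _pmass.Composition()
    for ch in p.sequence:
        try:
            comp += _AA_COMP[ch]
        except KeyError:
            raise ValueError(f"unknown residue code {ch!r} in {p.sequence!r}") from None
    comp += _WATER
    if p.n_term == "acetyl":
        comp += _ACETYL
    if p.c_term == "amide":
        comp += _AMIDE_DELTA
    if p.n_disulfides:
        comp -= _H2 * p.n_disulfides
    return comp


def compute_mass(p: PeptideSpec) -> MassResult:
    """Neutral monoisotopic and average masses of a modified peptide."""
    comp = _composition(p)
    mono = _pmass.calculate_mass(composition=comp)
    avg = _pmass.calculate_mass(composition=comp, average=True)
    delta: dict[str, float] = {}
    if p.n_term == "acetyl":
        delta["acetyl"] = _pmass.calculate_mass(composition=_ACETYL)
    if p.c_term == "amide":
        delta["amide"] = _pmass.calculate_mass(composition=_AMIDE_DELTA)
    if p.n_disulfides:
        delta["disulfides"] = -p.n_disulfides * _pmass.calculate_mass(composition=_H2)
    return MassResult(mono_neutral=mono, avg_neutral=avg, composition_delta=delta)


def mass_delta(p: PeptideSpec, q: PeptideSpec) -> float:
    """Monoisotopic neutral mass difference p - q, Da."""
    return compute_mass(p).mono_neutral - compute_mass(q).mono_neutral
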