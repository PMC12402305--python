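"""Unit conversions used throughout the model.

All molecular species are carried as nM concentrations within their
compartment volume; cells are absolute counts.  The receptors/cell to nM
conversion happens exactly once, at state assembly.
"""

from __future__ import annotations

AVOGADRO = 6.02214076e23

#: default molar masses, g/mol
MW_BSAB = 148_000.0     # IgG-scale bispecific antibody
MW_SBCMA = 20_000.0     # full-length shed BCMA, configurable at call sites


def receptors_to_nM(count: float, volume_L: float) -> float:
    """Convert a receptor (or molecule) count to nM within ``volume_L``."""
    return count / AVOGADRO / volume_L * 1e9


def nM_to_count(conc_nM: float, volume_L: float) -> float:
    """Inverse of :func:`receptors_to_nM`."""
    return conc_nM * 1e-9 * AVOGADRO * volume_L


def mg_to_nmol(mg: float, mw: float = MW_BSAB) -> float:
    """Convert a drug dose in mg to nmol (``mw`` in g/mol)."""
    return mg * 1e-3 / mw * 1e9


def ngml_to_nM(ngml: float, mw: float = MW_SBCMA) -> float:
    """Convert ng/mL to nM (``mw`` in g/mol)."""
    return ngml * 1e3 / mw


def nM_to_ngml(conc_nM: float, mw: float = MW_SBCMA) -> float:
    return conc_nM * mw / 1e3
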