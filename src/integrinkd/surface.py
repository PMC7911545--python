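"""RGD ligand surface chemistry.

Converts the composition of a mixed PLL-g-PEG / PLL-g-PEG-RGD coating into
the molar and number surface density of RGD motifs and the mean
ligand-ligand distance under hexagonal packing.

The coating is a poly-L-lysine backbone (``n_lys`` lysines on average) with
PEG chains grafted at a ratio of ``grafting_ratio`` lysines per chain; a
fraction ``p_functional`` of the chains carries an RGD peptide, and the
functionalized copolymer (PPR) is mixed with its bare counterpart (PP) at a
percentage ``q``.  The adsorbed surface mass density ``gamma`` closes the
mass balance:

    rho_RGD = (gamma / M_pol) * (q/100) * (n_lys / g) * (p/100)

Internal canonical units: lengths in um, areas in um^2, molar densities in
mol/um^2; spacing is reported in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidParameterError

#: Avogadro constant, exact SI value, 1/mol.
AVOGADRO = 6.02214076e23

# ng/cm^2 -> g/um^2  (1 ng = 1e-9 g, 1 cm^2 = 1e8 um^2)
_NG_PER_CM2_TO_G_PER_UM2 = 1e-17


@dataclass(frozen=True)
class PolymerSpec:
    """Composition of a PPR/PP coating.

    Parameters
    ----------
    gamma : float
        Adsorbed polymer surface mass density, ng/cm^2.
    m_pol : float
        Copolymer molecular weight, kDa.
    n_lys : float
        Mean number of lysines per PLL backbone.
    grafting_ratio : float
        Lysines per grafted PEG chain (g).
    p_functional : float
        Percentage of PEG chains carrying an RGD peptide, in (0, 100].
    q : float
        PPR-to-PP mixing ratio, percent in [0, 100].

    Defaults are the coating used throughout the assay design:
    PLL(20)-g(3.5)-PEG(2) with 14.7% RGD-functionalized chains adsorbing
    at 97 ng/cm^2.
    """

    gamma: float = 97.0
    m_pol: float = 107.76
    n_lys: float = 136.82
    grafting_ratio: float = 3.5
    p_functional: float = 14.7
    q: float = 100.0

    def __post_init__(self) -> None:
        for name in ("gamma", "m_pol", "n_lys", "grafting_ratio", "p_functional"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        if not (0.0 <= self.q <= 100.0):
            raise InvalidParameterError("q is a percentage and must lie in [0, 100]")
        if self.p_functional > 100.0:
            raise InvalidParameterError("p_functional is a percentage and must be <= 100")


@dataclass(frozen=True)
class RGDLattice:
    """RGD surface density and the implied hexagonal lattice spacing.

    Attributes
    ----------
    rho_molar : float
        Molar RGD surface density, mol/um^2.
    rho_number : float
        RGD number density ``rho_molar * N_A``, 1/um^2.
    spacing : float
        Mean RGD-RGD distance under hexagonal packing, nm.
        ``math.inf`` when the density is zero.
    """

    rho_molar: float
    rho_number: float
    spacing: float


def rgd_density(spec: PolymerSpec) -> RGDLattice:
    """Compute the RGD surface density implied by a coating composition.

    The adsorbed mass density divided by the copolymer molecular weight
    gives the molar density of backbones; scaling by the PPR fraction, the
    number of PEG chains per backbone (``n_lys / grafting_ratio``) and the
    functionalized fraction yields the molar RGD density, linear in ``q``.

    Returns an :class:`RGDLattice`; for ``q = 0`` the number density is zero
    and the spacing is reported as infinite.
    """
    gamma_g_um2 = spec.gamma * _NG_PER_CM2_TO_G_PER_UM2
    m_pol_g_mol = spec.m_pol * 1000.0  # kDa -> g/mol
    rho_molar = (
        gamma_g_um2
        / m_pol_g_mol
        * (spec.q / 100.0)
        * (spec.n_lys / spec.grafting_ratio)
        * (spec.p_functional / 100.0)
    )
    rho_number = rho_molar * AVOGADRO
    spacing = rgd_spacing(rho_number) if rho_number > 0 else math.inf
    return RGDLattice(rho_molar=rho_molar, rho_number=rho_number, spacing=spacing)


def rgd_spacing(rho_number: float) -> float:
    """Mean ligand-ligand distance for a hexagonal arrangement, in nm.

    For a hexagonal lattice of number density ``nu`` (1/um^2) the
    nearest-neighbour distance is ``sqrt((2/sqrt(3)) / nu)`` um.

    Raises
    ------
    InvalidParameterError
        If ``rho_number`` is not strictly positive; a zero density has no
        finite spacing and must be handled by the caller.
    """
    if not rho_number > 0:
        raise InvalidParameterError("rho_number must be strictly positive for a finite spacing")
    spacing_um = math.sqrt((2.0 / math.sqrt(3.0)) / rho_number)
    return spacing_um * 1000.0
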