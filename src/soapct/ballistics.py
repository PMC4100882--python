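"""Shot-level bookkeeping: deposited energy, unit conversions, ratios.

The deposited energy of a shot is the kinetic energy released inside the
block: the entry kinetic energy minus the kinetic energy carried out by
exiting fragments,

    E = 1/2 m_in v_in^2 - 1/2 m_exit v_out^2

with masses in kg and speeds in m/s.  Bullet weights are conventionally
quoted in both grams and grains (1 gr = 0.06479891 g exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GRAIN_G",
    "Bullet",
    "BULLETS",
    "ShotRecord",
    "deposited_energy",
    "grams_to_grains",
    "retained_mass_fraction",
    "energy_volume_ratio",
]

#: Avoirdupois grain in grams (exact definition).
GRAIN_G = 0.06479891


@dataclass(frozen=True)
class Bullet:
    """Catalogue entry for a bullet type."""

    abbreviation: str
    name: str
    materials: str
    #: terminal-ballistic class: how the bullet releases its energy
    bullet_type: str  # "dimensionally stable" | "fragmenting" | "deforming"
    caliber_mm: float
    mass_g: float
    #: impact speeds tested for this bullet (m/s)
    speeds_mps: tuple[float, ...]


#: The four commercially available 7.62 mm bullets of the study design:
#: a dimensionally stable brass bullet (ILS), a partially fragmenting
#: copper bullet with an aluminum tip (TAG), a deforming copper bullet with
#: a drilled tip hole (TSX), and a deforming lead-core semi-jacketed
#: bullet (NVU).
BULLETS: dict[str, Bullet] = {
    "ILS": Bullet("ILS", "Impala LS", "Brass", "dimensionally stable",
                  7.62, 8.45, (600.0, 700.0, 800.0, 900.0)),
    "TAG": Bullet("TAG", "Brennecke TAG", "Copper", "fragmenting",
                  7.62, 10.07, (550.0, 650.0, 750.0, 850.0)),
    "TSX": Bullet("TSX", "Barnes TSX", "Copper", "deforming",
                  7.62, 10.71, (550.0, 650.0, 750.0, 850.0)),
    "NVU": Bullet("NVU", "Norma Vulcan", "Lead/Copper", "deforming",
                  7.62, 11.68, (500.0, 600.0, 700.0, 800.0)),
}


@dataclass
class ShotRecord:
    """One shot into one soap block.

    ``speed_out_mps`` and ``mass_exit_g`` are 0 when nothing exited the
    block.  ``deposited_energy_j`` is derived; ``cavity_volume_ml`` is
    attached after image analysis.
    """

    bullet: str
    caliber_mm: float
    mass_initial_g: float
    speed_in_mps: float
    speed_out_mps: float = 0.0
    mass_exit_g: float = 0.0
    repetition: int = 0
    deposited_energy_j: float = field(init=False, default=0.0)
    cavity_volume_ml: float | None = None

    def __post_init__(self) -> None:
        self.deposited_energy_j = deposited_energy(
            self.mass_initial_g, self.speed_in_mps,
            self.mass_exit_g, self.speed_out_mps)


def deposited_energy(mass_initial_g: float, speed_in_mps: float,
                     mass_exit_g: float = 0.0,
                     speed_out_mps: float = 0.0) -> float:
    """Energy (J) released inside the block.

    ``1/2 m_in v_in^2 - 1/2 m_exit v_out^2`` with masses converted g→kg.

    Raises
    ------
    ValueError
        If the exiting mass exceeds the initial mass, a speed is negative,
        or the exiting kinetic energy exceeds the entry kinetic energy.
    """
    if mass_initial_g <= 0:
        raise ValueError("initial mass must be positive")
    if not 0 <= mass_exit_g <= mass_initial_g:
        raise ValueError("exit mass must lie in [0, initial mass]")
    if speed_in_mps < 0 or speed_out_mps < 0:
        raise ValueError("speeds must be nonnegative")
    e_in = 0.5 * (mass_initial_g / 1000.0) * speed_in_mps**2
    e_out = 0.5 * (mass_exit_g / 1000.0) * speed_out_mps**2
    if e_out > e_in:
        raise ValueError("exiting kinetic energy exceeds entry kinetic energy")
    return e_in - e_out


def grams_to_grains(mass_g: float, ndigits: int | None = 2) -> float:
    """Convert a mass in grams to grains (1 gr = 0.06479891 g).

    Rounded to ``ndigits`` decimals for display by default; pass
    ``ndigits=None`` for the unrounded value.
    """
    if mass_g < 0:
        raise ValueError("mass must be nonnegative")
    gr = mass_g / GRAIN_G
    return gr if ndigits is None else round(gr, ndigits)


def retained_mass_fraction(mass_initial_g: float, mass_exit_g: float) -> float:
    """Relative weight of the exiting fragments, in percent of initial mass."""
    if mass_initial_g <= 0:
        raise ValueError("initial mass must be positive")
    if not 0 <= mass_exit_g <= mass_initial_g:
        raise ValueError("exit mass must lie in [0, initial mass]")
    return 100.0 * mass_exit_g / mass_initial_g


def energy_volume_ratio(volume_ml: float, energy_j: float) -> float:
    """Cavity volume per deposited energy (mL/J).

    A constant ratio over energy indicates a linear volume–energy law; a
    ratio that rises linearly with energy indicates a quadratic law.
    """
    if energy_j <= 0:
        raise ValueError("deposited energy must be positive")
    return volume_ml / energy_j
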