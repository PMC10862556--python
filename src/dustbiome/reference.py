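"""Reference constants: crustal composition and oxide conversion factors.

Upper continental crust (UCC) element abundances follow the Rudnick & Gao
(2003) compilation (Treatise on Geochemistry, vol. 3), in micrograms of
element per gram of crust.  Only the elements used by the ternary mixing
analysis and the mineral-mass reconstruction are tabulated; the table can
be overridden through configuration.
"""

from __future__ import annotations

#: UCC abundances, µg/g (Rudnick & Gao 2003).
UCC_ABUNDANCES: dict[str, float] = {
    "Al": 81_500.0,
    "Si": 311_400.0,
    "Ca": 25_700.0,
    "Fe": 39_200.0,
    "Ti": 3_800.0,
    "K": 23_200.0,
    "Na": 24_300.0,
    "Mg": 15_000.0,
    "V": 97.0,
    "Ni": 47.0,
    "La": 31.0,
    "Ce": 63.0,
}

#: Conventional crustal oxide multipliers used for the reconstructed
#: measured mineral material (RMMM): each measured crustal element is
#: scaled to its common oxide form (Al2O3, SiO2, CaO, Fe2O3, TiO2).
OXIDE_FACTORS: dict[str, float] = {
    "Al": 1.89,
    "Si": 2.14,
    "Ca": 1.40,
    "Fe": 1.43,
    "Ti": 1.67,
}

#: Elements whose oxides constitute the RMMM sum.
RMMM_ELEMENTS: tuple[str, ...] = ("Al", "Si", "Ca", "Fe", "Ti")
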