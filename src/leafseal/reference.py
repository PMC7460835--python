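"""Published reference values for the two study species.

These are the literature-reported median mechanical properties and
median parenchyma cell geometries of *D. ecklonis* and *D. cooperi*
leaves.  They serve as inputs to the derived computations (interspecific
ratio tables, turgor-based parenchyma moduli) and as conformance anchors
for the worked examples; they are not measured by this package.
"""

from __future__ import annotations

from .biomechanics import ComparisonRow
from .morphometry import CellGeometry

__all__ = [
    "MECHANICAL_PROPERTIES",
    "PARENCHYMA_INPUTS",
    "CELL_WALL_MODULUS_MPA",
]

#: elastic modulus of parenchyma cell walls, MPa (literature value)
CELL_WALL_MODULUS_MPA = 5.00

#: reported medians (species order: D. ecklonis first, D. cooperi second)
#: with standard errors, sample sizes and the significance level of the
#: interspecific rank-sum comparison expressed as an upper p bound
#: (None: not applicable / not significant recorded as p = 1).
MECHANICAL_PROPERTIES: list[ComparisonRow] = [
    ComparisonRow("Elastic modulus, leaf (MPa)",
                  1.21, 0.72, 0.11, 0.14, 14, 18, p=0.001),
    ComparisonRow("Elastic modulus, central vascular strand (MPa)",
                  63.68, 32.80, 7.52, 5.96, 9, 8, p=0.01),
    ComparisonRow("Elastic modulus, epidermis transverse (MPa)",
                  2.88, 3.62, 0.40, 0.27, 6, 10, p=0.05),
    ComparisonRow("Elastic modulus, epidermis longitudinal (MPa)",
                  3.51, 5.27, 1.21, 0.85, 8, 10, p=1.0),
    ComparisonRow("Elastic modulus, hydrenchyma (MPa)", 0.26, 0.23),
    ComparisonRow("Elastic modulus, chlorenchyma (MPa)", 0.26, 0.27),
    ComparisonRow("Tensile strength, leaf (MPa)",
                  0.16, 0.09, 0.01, 0.01, 14, 13, p=0.001),
    ComparisonRow("Tensile strength, central vascular strand (MPa)",
                  10.99, 8.80, 0.70, 0.76, 9, 8, p=0.01),
    ComparisonRow("Tensile strength, epidermis transverse (MPa)",
                  0.58, 1.25, 0.10, 0.07, 6, 10, p=0.01),
    ComparisonRow("Tensile strength, epidermis longitudinal (MPa)",
                  0.70, 1.54, 0.26, 0.11, 8, 10, p=0.01),
    ComparisonRow("Poisson's ratio, leaf",
                  0.35, 0.29, 0.03, 0.03, 14, 18, p=0.05),
    ComparisonRow("Turgor, parenchyma (MPa)",
                  0.05, 0.04, 0.002, 0.003, 36, 44, p=1.0),
]

#: median cell geometry, turgor and Poisson's ratio per species/tissue,
#: inputs of the turgor-based parenchyma modulus
PARENCHYMA_INPUTS: dict[tuple[str, str], dict] = {
    ("D. ecklonis", "hydrenchyma"): {
        "cell": CellGeometry(d_c_um=84.73, t_cw_um=0.37),
        "P_mpa": 0.05, "nu": 0.35,
    },
    ("D. ecklonis", "chlorenchyma"): {
        "cell": CellGeometry(d_c_um=73.72, t_cw_um=0.35),
        "P_mpa": 0.05, "nu": 0.35,
    },
    ("D. cooperi", "hydrenchyma"): {
        "cell": CellGeometry(d_c_um=92.00, t_cw_um=0.42),
        "P_mpa": 0.04, "nu": 0.29,
    },
    ("D. cooperi", "chlorenchyma"): {
        "cell": CellGeometry(d_c_um=62.50, t_cw_um=0.42),
        "P_mpa": 0.04, "nu": 0.29,
    },
}
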