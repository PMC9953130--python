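"""Reference model compositions for the two source kinase structures.

Stand-in hypotheses reproducing the published feature inventories of the two
inhibitor-bound ACK1 structures used to seed the hybrid model:

* ``1U4D`` (DBQ-bound), "Pharm A": 3 HBD, 2 HBA, 2 HYP, 1 PI — H-bond
  features complementary to the hinge (A208, E206), catalytic lysine (K158)
  and DFG aspartate (D270).
* ``3EQR`` (T74-bound), "Pharm B": 4 HYP, 2 HBD, 1 HBA — H-bond features
  complementary to the gatekeeper (T205) and hinge (A208, E206).

The coordinates are synthetic stand-ins (the proprietary generator's centers
are not published): they are laid out in a common frame so that features
annotated to the same residue from both structures fall within the default
cluster radius and merge, while all other same-kind features stay separate.
The residue annotations are the scientifically meaningful content.
"""

from __future__ import annotations

from .pharmacophore import PharmacophoreFeature, PharmacophoreModel

__all__ = ["pharm_a_standin", "pharm_b_standin"]


def _f(kind, center, residue=None, source="?", projected=None):
    return PharmacophoreFeature(kind, center, 1.6, projected, 2.2,
                                residue, source)


def pharm_a_standin() -> PharmacophoreModel:
    """Eight-feature hypothesis of the DBQ-bound structure (3 HBD, 2 HBA,
    2 HYP, 1 PI)."""
    s = "1U4D"
    feats = [
        _f("HBA", (0.0, 0.0, 0.0), "A208", s, projected=(0.0, -2.0, 0.0)),
        _f("HBA", (6.0, 0.0, 0.0), "D270", s, projected=(8.0, 0.0, 0.0)),
        _f("HBD", (0.0, 4.0, 0.0), "E206", s),
        _f("HBD", (6.0, 4.0, 0.0), "K158", s),
        _f("HBD", (3.0, 6.0, 0.0), "D134", s),
        _f("HYP", (3.0, -4.0, 0.0), "L132", s),
        _f("HYP", (-3.0, -4.0, 0.0), "V140", s),
        _f("PI", (0.0, 8.0, 0.0), None, s),
    ]
    return PharmacophoreModel("pharm-A", feats, [s], s)


def pharm_b_standin() -> PharmacophoreModel:
    """Seven-feature hypothesis of the T74-bound structure (4 HYP, 2 HBD,
    1 HBA)."""
    s = "3EQR"
    feats = [
        _f("HBA", (0.5, 0.0, 0.0), "A208", s, projected=(0.5, -2.0, 0.0)),
        _f("HBD", (-4.0, 2.0, 0.0), "T205", s),
        _f("HBD", (0.3, 4.0, 0.0), "E206", s),
        _f("HYP", (3.2, -4.0, 0.0), "L132", s),
        _f("HYP", (-6.0, -2.0, 0.0), "M203", s),
        _f("HYP", (-6.0, 2.0, 0.0), "M203", s),
        _f("HYP", (8.0, -3.0, 0.0), "L259", s),
    ]
    return PharmacophoreModel("pharm-B", feats, [s], s)
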