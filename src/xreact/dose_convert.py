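"""Weight-proportional cell-dose translation between species.

Human adoptive-cell-therapy doses are prescribed per kilogram of body
weight; xenograft experiments dose per mouse. Under simple weight-based
(per-kg) scaling the mouse-equivalent of a human dose is cells/kg times the
mouse mass, and the fold-excess of an experimental dose over the
human-proportional dose is their ratio. Only linear per-kg scaling is
implemented; body-surface-area or allometric conversion is out of scope.
"""

from __future__ import annotations

#: Conventional adult NSG mouse body mass in kilograms (20 g); overridable
#: everywhere it is used.
DEFAULT_MOUSE_MASS_KG: float = 0.02


class DoseError(ValueError):
    """Invalid dose-conversion input."""


def mouse_equivalent_dose(
    cells_per_kg: float, mouse_mass: float = DEFAULT_MOUSE_MASS_KG
) -> float:
    """Mouse dose (cells/mouse) proportional to a human dose (cells/kg).

    Exact product ``cells_per_kg * mouse_mass``; both inputs must be
    positive.
    """
    if cells_per_kg <= 0:
        raise DoseError(f"cells_per_kg {cells_per_kg} must be positive")
    if mouse_mass <= 0:
        raise DoseError(f"mouse_mass {mouse_mass} must be positive")
    return cells_per_kg * mouse_mass


def fold_excess(model_dose: float, proportional_dose: float) -> float:
    """Ratio of an experimental per-mouse dose to the human-proportional dose."""
    if proportional_dose <= 0:
        raise DoseError(f"proportional_dose {proportional_dose} must be positive")
    if model_dose < 0:
        raise DoseError(f"model_dose {model_dose} must be nonnegative")
    return model_dose / proportional_dose
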