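"""Metabolic ³²P-labeling math.

Cultures are spiked with carrier-free [³²P]-orthophosphate; the cold
phosphate of the growth medium dilutes the tracer, so each of a tRNA's
~length phosphates is radioactive independently with probability
1/dilution. The expected label count per molecule is therefore
lambda = length / dilution, and the number of ³²P atoms per molecule is
Poisson(lambda) — at typical spike levels lambda << 1, so molecules carry
at most one label and spot intensity is linear in molecule count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "LabelingParams",
    "LabelingDerived",
    "spike_molarity_umol_per_l",
    "dilution_factor",
    "labels_per_molecule",
    "derive",
]


@dataclass(frozen=True)
class LabelingParams:
    """Labeling conditions.

    spike_activity_uci_per_ml    added tracer activity (uCi/ml of culture)
    specific_activity_ci_per_mmol  tracer specific activity (Ci/mmol)
    media_phosphate_mmol_per_l   cold orthophosphate of the medium (mM);
                                 22 mM matches M9-style minimal media
    trna_length_nt               phosphates per tRNA molecule (~length)
    """

    spike_activity_uci_per_ml: float = 10.0
    specific_activity_ci_per_mmol: float = 1.0
    media_phosphate_mmol_per_l: float = 22.0
    trna_length_nt: int = 76

    def __post_init__(self) -> None:
        for name in (
            "spike_activity_uci_per_ml",
            "specific_activity_ci_per_mmol",
            "media_phosphate_mmol_per_l",
            "trna_length_nt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class LabelingDerived:
    dilution_factor: float    # fold dilution of tracer by cold phosphate
    lam: float                # expected 32P atoms per tRNA molecule
    p_multilabel: float       # P(>= 2 atoms) under the Poisson model

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_multilabel <= 1.0:
            raise ValueError("p_multilabel must be in [0, 1]")


def spike_molarity_umol_per_l(
    spike_activity_uci_per_ml: float, specific_activity_ci_per_mmol: float
) -> float:
    """Molar concentration of the spiked tracer in umol/L.

    uCi/ml divided by Ci/mmol: 10 uCi/ml at 1 Ci/mmol is 10 umol/L.
    """
    if spike_activity_uci_per_ml <= 0 or specific_activity_ci_per_mmol <= 0:
        raise ValueError("activities must be > 0")
    # (uCi/ml) / (Ci/mmol) = 1e-6 Ci/ml / (Ci/mmol) = 1e-6 mmol/ml = umol/L
    return spike_activity_uci_per_ml / specific_activity_ci_per_mmol


def dilution_factor(params: LabelingParams) -> float:
    """Isotopic dilution: cold media phosphate over spiked tracer molarity.

    The tracer's own contribution to the phosphate pool is negligible and
    is not added to the numerator.
    """
    spike_umol = spike_molarity_umol_per_l(
        params.spike_activity_uci_per_ml, params.specific_activity_ci_per_mmol
    )
    return params.media_phosphate_mmol_per_l * 1000.0 / spike_umol


def labels_per_molecule(length_nt: int, dilution: float) -> tuple[float, float]:
    """Expected ³²P atoms per molecule and P(>= 2 atoms).

    lambda = length/dilution (one independent labeling chance per phosphate);
    p_multilabel = 1 - e^(-lambda)(1 + lambda), the Poisson tail beyond one.
    """
    if dilution <= 0:
        raise ValueError("dilution must be > 0")
    lam = length_nt / dilution
    p_multi = 1.0 - math.exp(-lam) * (1.0 + lam)
    return lam, p_multi


def derive(params: LabelingParams | None = None) -> LabelingDerived:
    """Full derived report for a labeling condition."""
    params = params or LabelingParams()
    fold = dilution_factor(params)
    lam, p_multi = labels_per_molecule(params.trna_length_nt, fold)
    return LabelingDerived(dilution_factor=fold, lam=lam, p_multilabel=p_multi)
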