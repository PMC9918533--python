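"""Endpoint registry: what is measured, on what scale, and which way is worse.

Every measurement column in a cohort table must be declared here.  The
registry drives normalization (theoretical bounds for cognitive scales,
percentile clipping for imaging/CSF, centiloid clipping for amyloid PET)
and the orientation convention used throughout the package: after
normalization 0 is the most normal value and 1 the maximum pathological
change, for every endpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable

MODALITIES = ("cognitive", "mri", "csf", "pet_amyloid", "pet_tau")


@dataclass(frozen=True)
class EndpointSpec:
    """Declaration of a single longitudinal endpoint.

    Parameters
    ----------
    name : str
        Column name in cohort files (e.g. ``"mmse"``).
    modality : str
        One of ``cognitive``, ``mri``, ``csf``, ``pet_amyloid``, ``pet_tau``.
        Missing-data fractions and normalization strategy are per modality.
    higher_is_worse : bool
        Orientation of the native scale.  ``False`` for MMSE, hippocampal
        volume and CSF A-beta 1-42, which decrease with disease.
    unit : str
        Native unit, for reporting only.
    native_best, native_worst : float, optional
        Theoretical bounds of the native scale.  Required for cognitive
        endpoints (e.g. MMSE best 30 / worst 0, ADAS-Cog13 best 0 /
        worst 85); optional affine bounds for other modalities when a
        fixed rather than data-driven normalization is wanted.
    """

    name: str
    modality: str
    higher_is_worse: bool
    unit: str = ""
    native_best: float | None = None
    native_worst: float | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r} for endpoint {self.name!r}")
        if self.modality == "cognitive":
            if self.native_best is None or self.native_worst is None:
                raise ValueError(f"cognitive endpoint {self.name!r} needs theoretical bounds")
            if not (math.isfinite(self.native_best) and math.isfinite(self.native_worst)):
                raise ValueError(f"cognitive endpoint {self.name!r} bounds must be finite")
            if self.native_best == self.native_worst:
                raise ValueError(f"cognitive endpoint {self.name!r} bounds must differ")

    @property
    def has_bounds(self) -> bool:
        return self.native_best is not None and self.native_worst is not None


class EndpointRegistry(Dict[str, EndpointSpec]):
    """Mapping endpoint name -> :class:`EndpointSpec`, one spec per name."""

    def __init__(self, specs: Iterable[EndpointSpec] = ()):  # noqa: D107
        super().__init__()
        for spec in specs:
            self.add(spec)

    def add(self, spec: EndpointSpec) -> None:
        if spec.name in self:
            raise ValueError(f"duplicate endpoint {spec.name!r} in registry")
        self[spec.name] = spec

    def by_modality(self, modality: str) -> list[str]:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        return [name for name, s in self.items() if s.modality == modality]


def default_registry() -> EndpointRegistry:
    """The standard nine-endpoint panel of an AD progression study.

    Cognitive scales carry their theoretical bounds; volumetric endpoints
    are in percent of intracranial volume; CSF biomarkers are expected on
    the harmonized (unitless) scale; amyloid PET in centiloids and tau PET
    as SUVR.
    """
    return EndpointRegistry(
        [
            EndpointSpec("mmse", "cognitive", higher_is_worse=False, unit="points",
                         native_best=30.0, native_worst=0.0),
            EndpointSpec("adas13", "cognitive", higher_is_worse=True, unit="points",
                         native_best=0.0, native_worst=85.0),
            EndpointSpec("cdrsb", "cognitive", higher_is_worse=True, unit="points",
                         native_best=0.0, native_worst=18.0),
            EndpointSpec("hippocampus_icv", "mri", higher_is_worse=False, unit="% ICV"),
            EndpointSpec("ventricles_icv", "mri", higher_is_worse=True, unit="% ICV"),
            EndpointSpec("csf_abeta42", "csf", higher_is_worse=False, unit="harmonized"),
            EndpointSpec("csf_ptau181", "csf", higher_is_worse=True, unit="harmonized"),
            EndpointSpec("amyloid_pet_cl", "pet_amyloid", higher_is_worse=True, unit="CL"),
            EndpointSpec("tau_pet_suvr", "pet_tau", higher_is_worse=True, unit="SUVR"),
        ]
    )
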