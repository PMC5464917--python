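"""The Lyman-Kutcher-Burman (LKB) NTCP model.

The model maps a non-uniform organ dose distribution to a normal-tissue
complication probability (NTCP) through three parameters:

* ``n`` — volume-effect exponent (n = 1 reduces the dose summary to the
  mean organ dose; n -> 0 to the maximum dose);
* ``m`` — steepness of the probit dose-response (smaller m = steeper);
* ``TD50(1)`` — dose giving 50% complication probability under uniform
  whole-organ irradiation.

The Kutcher-Burman reduction collapses a differential DVH with partial
volumes ``v_i`` at doses ``D_i`` into the generalized (equivalent uniform)
dose ``EUD = (sum_i v_i D_i^(1/n))^n`` and the response is
``NTCP = Phi((EUD - TD50(1)) / (m * TD50(1)))`` with Phi the standard
normal CDF. The equivalent effective-volume form — partial volume
``v_eff`` at a reference dose ``D_ref`` with tolerance
``TD50(v) = TD50(1) * v^-n`` — is provided as well; the two are related by
the identity ``EUD = D_ref * v_eff^n``.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from importlib import resources

import numpy as np
from scipy.special import logsumexp, ndtr

from .dvh import DoseVolumeHistogram, _as_differential, max_dose
from .errors import ParameterError, RangeError


@dataclass(frozen=True)
class LKBParameters:
    """The LKB triple (n, m, TD50(1)); all strictly positive, n and m <= 5."""

    n: float
    m: float
    td50_1_gy: float

    def __post_init__(self) -> None:
        if not (self.n > 0 and self.m > 0 and self.td50_1_gy > 0):
            raise ParameterError("LKB parameters must be strictly positive")
        if self.n > 5 or self.m > 5:
            raise ParameterError("n and m above 5 are outside the sane model range")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "LKBParameters":
        d = json.loads(text)
        return cls(n=d["n"], m=d["m"], td50_1_gy=d["td50_1_gy"])


def load_preset(name: str) -> LKBParameters:
    """Load a named parameter preset shipped with the package.

    ``breast_imrt_lung`` is the triple fitted to a 109-patient postoperative
    breast-IMRT cohort (n=0.912, m=0.437, TD50(1)=17.211 Gy);
    ``emami_burman_lung`` is the classical whole-lung literature fit
    (n=0.87, m=0.18, TD50(1)=24.5 Gy).
    """
    text = resources.files("lungntcp.data").joinpath("lkb_presets.json").read_text()
    presets = json.loads(text)
    if name not in presets:
        raise ParameterError(f"unknown preset {name!r}; have {sorted(presets)}")
    return LKBParameters(**presets[name])


def list_presets() -> list[str]:
    text = resources.files("lungntcp.data").joinpath("lkb_presets.json").read_text()
    return sorted(json.loads(text))


def standard_normal_cdf(t):
    """Phi(t), the standard normal CDF (erf-based; abs. accuracy < 1e-12)."""
    return ndtr(t) if np.ndim(t) else float(ndtr(t))


def eud(h: DoseVolumeHistogram, n: float) -> float:
    """Generalized equivalent uniform dose ``(sum v_i D_i^(1/n))^n`` in Gy.

    Computed in log space (log-sum-exp) so that small ``n`` (large exponent
    1/n) does not overflow; zero-dose bins contribute zero by continuity.
    """
    if n <= 0:
        raise ParameterError("volume exponent n must be positive")
    d = _as_differential(h)
    mask = (d.volumes > 0) & (d.doses_gy > 0)
    if not mask.any():
        return 0.0
    logs = np.log(d.volumes[mask]) + np.log(d.doses_gy[mask]) / n
    return float(np.exp(n * logsumexp(logs)))


def effective_volume(
    h: DoseVolumeHistogram, n: float, reference_dose_gy: float | None = None
) -> float:
    """Kutcher-Burman effective volume ``sum v_i (D_i / D_ref)^(1/n)``.

    The fraction of the organ which, uniformly irradiated at
    ``reference_dose_gy`` (default: the histogram's maximum dose), is
    equivalent to the actual distribution. In [0, 1] when the reference is
    the maximum dose.
    """
    if n <= 0:
        raise ParameterError("volume exponent n must be positive")
    if reference_dose_gy is None:
        reference_dose_gy = max_dose(h)
    if reference_dose_gy <= 0:
        raise ParameterError("reference dose must be positive")
    d = _as_differential(h)
    mask = (d.volumes > 0) & (d.doses_gy > 0)
    if not mask.any():
        return 0.0
    logs = np.log(d.volumes[mask]) + (
        np.log(d.doses_gy[mask]) - np.log(reference_dose_gy)
    ) / n
    return float(np.exp(logsumexp(logs)))


def ntcp_from_eud(eud_gy: float, params: LKBParameters) -> float:
    """Probit dose response ``Phi((EUD - TD50(1)) / (m * TD50(1)))``."""
    if eud_gy < 0:
        raise RangeError("EUD must be nonnegative")
    t = (eud_gy - params.td50_1_gy) / (params.m * params.td50_1_gy)
    return float(ndtr(t))


def ntcp_for_dvh(h: DoseVolumeHistogram, params: LKBParameters) -> float:
    """NTCP of a dose distribution: reduction to EUD, then the probit response."""
    return ntcp_from_eud(eud(h, params.n), params)


def ntcp_for_patient(record, params: LKBParameters) -> float:
    """NTCP of a patient's ipsilateral-lung DVH under ``params``."""
    return ntcp_for_dvh(record.dvh, params)
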