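"""CT dosimetry for the dynamic acquisition protocol.

Quantities follow head-CT dosimetry conventions: the skin dose is estimated
by CTDI_100, which for head acquisitions equals CTDI_vol (conversion factor
1); the effective dose is the dose–length product times the head conversion
factor 0.0023 mSv/(mGy·cm).  Both factors are convention-dependent and
overridable.  Values are kept at full precision; rounding happens only at
report time (2 decimals in summaries, 4 in tables).
"""

from __future__ import annotations

from dataclasses import dataclass

#: CTDI_100 = CTDI_vol × this factor for head acquisitions.
HEAD_CTDI_FACTOR = 1.0
#: Effective dose (mSv) = DLP (mGy·cm) × this head-region factor.
HEAD_DLP_FACTOR = 0.0023


def effective_dose(dlp: float, dlp_factor: float = HEAD_DLP_FACTOR) -> float:
    """Effective dose (mSv) from a dose–length product (mGy·cm)."""
    if dlp < 0:
        raise ValueError("DLP must be non-negative")
    return dlp * dlp_factor


def skin_dose(ctdi_vol: float, ctdi_factor: float = HEAD_CTDI_FACTOR) -> float:
    """Skin dose estimate CTDI_100 (mGy) from CTDI_vol (mGy)."""
    if ctdi_vol < 0:
        raise ValueError("CTDI_vol must be non-negative")
    return ctdi_vol * ctdi_factor


def dlp_from_geometry(ctdi_vol: float, length_cm: float) -> float:
    """Dose–length product (mGy·cm) = CTDI_vol × irradiated length."""
    if ctdi_vol < 0 or length_cm < 0:
        raise ValueError("CTDI_vol and length must be non-negative")
    return ctdi_vol * length_cm


@dataclass
class DoseProtocol:
    """One acquisition protocol with its derived dose quantities."""

    kvp: float
    mas: float
    scan_time_s: float
    ctdi_vol: float                 # mGy
    scan_length_cm: float | None = None
    dlp: float | None = None        # mGy·cm; derived from geometry if absent
    ctdi_factor: float = HEAD_CTDI_FACTOR
    dlp_factor: float = HEAD_DLP_FACTOR

    def __post_init__(self) -> None:
        if self.dlp is None:
            if self.scan_length_cm is None:
                raise ValueError("either dlp or scan_length_cm must be given")
            self.dlp = dlp_from_geometry(self.ctdi_vol, self.scan_length_cm)

    @property
    def ctdi_100(self) -> float:
        return skin_dose(self.ctdi_vol, self.ctdi_factor)

    @property
    def d_eff(self) -> float:
        return effective_dose(self.dlp, self.dlp_factor)

    def as_dict(self) -> dict:
        return {
            "kvp": self.kvp,
            "mas": self.mas,
            "scan_time_s": self.scan_time_s,
            "ctdi_vol_mgy": self.ctdi_vol,
            "ctdi_100_mgy": self.ctdi_100,
            "dlp_mgy_cm": self.dlp,
            "d_eff_msv": round(self.d_eff, 4),
            "d_eff_msv_reported": round(self.d_eff, 2),
        }
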