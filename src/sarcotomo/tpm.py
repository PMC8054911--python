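"""Tropomyosin M/C-state localization by 37-nm sectioning.

Tropomyosin sits in the myosin-bound M state on A-band thin filaments
and in the calcium-induced C state in the I-band, the two azimuthal
positions ~21 deg apart.  Working on per-subunit azimuth offsets, a
filament is cut into 37 nm sections anchored at the A/I boundary
(section 1 = last A-band section, sections 2, 3, ... grow into the
I-band); each section is classified by the circular mean of its offsets
against the two reference angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError
from .helix import wrap180

__all__ = ["SectionState", "section_and_classify", "locate_transition"]


@dataclass
class SectionState:
    section_index: int
    y_start: float           # nm
    y_end: float             # nm
    mean_offset: float       # deg, circular mean
    state: str               # M / C / intermediate
    n_subunits: int


def _circ_mean(deg: np.ndarray) -> float:
    z = np.exp(1j * np.radians(deg))
    return float(np.degrees(np.angle(z.mean())))


def _classify(mean_offset: float, ref_m: float, ref_c: float,
              margin: float) -> str:
    dm = abs(float(wrap180(mean_offset - ref_m)))
    dc = abs(float(wrap180(mean_offset - ref_c)))
    if dm <= margin and dm < dc:
        return "M"
    if dc <= margin and dc < dm:
        return "C"
    return "intermediate"


def section_and_classify(subunits: pd.DataFrame, boundary_axial: float,
                         section_length: float = 37.0,
                         ref_m: float = 0.0, ref_c: float = 21.0,
                         margin: float = 5.0) -> list[SectionState]:
    """Cut one filament into sections and classify each M / C / intermediate.

    Parameters
    ----------
    subunits : table with columns y (Å) and tpm_offset (deg)
    boundary_axial : A/I boundary position (Å); +Y runs A-band -> I-band
    section_length : nm, default 37 (one tropomyosin unit)
    ref_m, ref_c : reference offsets (deg), nominally 21 deg apart
    margin : max circular distance (deg) for a hard M or C call

    Sections tile the filament without overlap; empty sections are
    skipped.  Classification is invariant under a common rotation of
    all offsets and both references.
    """
    if section_length <= 0:
        raise ParameterError("section_length must be > 0")
    if "tpm_offset" not in subunits.columns:
        raise ParameterError("subunits need a tpm_offset column")
    y = subunits["y"].to_numpy(dtype=float)
    if len(y) == 0:
        raise InsufficientDataError("no subunits")
    L = section_length * 10.0  # Å
    # section m covers [boundary + (m-2)L, boundary + (m-1)L); m=1 is the
    # last A-band section, larger m grows into the I-band
    m_lo = int(np.floor((y.min() - boundary_axial) / L)) + 1
    m_hi = int(np.ceil((y.max() - boundary_axial) / L)) + 1
    out = []
    for m in range(m_lo, m_hi + 1):
        lo = boundary_axial + (m - 2) * L
        hi = lo + L
        mask = (y >= lo) & (y < hi)
        if not mask.any():
            continue
        mean_off = _circ_mean(subunits.loc[mask, "tpm_offset"].to_numpy())
        out.append(SectionState(m, lo / 10.0, hi / 10.0, mean_off,
                                _classify(mean_off, ref_m, ref_c, margin),
                                int(mask.sum())))
    return out


def locate_transition(sections: list[SectionState]) -> Optional[int]:
    """Index of the first non-M section scanning from the A-band side.

    The observed pattern around the A/I boundary is (M, intermediate,
    C, C): the M-to-C switch completes essentially within one
    tropomyosin unit.  Returns None when every section is M
    (no transition).
    """
    if len(sections) < 1:
        raise InsufficientDataError("no sections")
    for s in sorted(sections, key=lambda s: s.section_index):
        if s.state != "M":
            return s.section_index
    return None
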