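"""Selection of residues that are persistently α-helical and persistently in
close contact with the partner protein over a trajectory.

A residue qualifies when (i) its DSSP code is 'H' in at least half of the
frames and (ii) it is within the contact cutoff (default 1.4 nm, the
electrostatic interaction cutoff) of any partner atom in at least half of the
frames; both cutoffs are inclusive (≥ 0.5).  Qualifying residues are
assembled into contiguous segments; segments shorter than four residues are
too short for fragment fitting and are dropped with a warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "StabilityProfile",
    "SelectionResult",
    "helical_fraction",
    "contact_fraction",
    "select_stable_contact_helix",
    "fraction_histogram",
    "parse_dssp",
    "read_ss_strings",
]

HELIX_CODE = "H"
MIN_SEGMENT = 4  # minimum residues for a fragment fit


@dataclass
class StabilityProfile:
    """Per-residue helical-presence and contact-presence ratios."""

    residue_ids: np.ndarray
    helical_fraction: np.ndarray
    contact_fraction: np.ndarray
    n_frames: int

    def __post_init__(self):
        self.residue_ids = np.asarray(self.residue_ids)
        self.helical_fraction = np.asarray(self.helical_fraction, dtype=float)
        self.contact_fraction = np.asarray(self.contact_fraction, dtype=float)
        n = len(self.residue_ids)
        if len(self.helical_fraction) != n or len(self.contact_fraction) != n:
            raise InputError("profile arrays must have equal length")
        for name in ("helical_fraction", "contact_fraction"):
            f = getattr(self, name)
            if np.any((f < 0) | (f > 1)):
                raise InputError(f"{name} must lie in [0, 1]")

    def to_dataframe(self, selected: Optional[np.ndarray] = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "residue_id": self.residue_ids,
                "helical_fraction": self.helical_fraction,
                "contact_fraction": self.contact_fraction,
            }
        )
        if selected is not None:
            df["selected"] = np.asarray(selected, dtype=bool)
        return df


@dataclass
class SelectionResult:
    """Contiguous residue segments passing both stability criteria."""

    selected_residues: np.ndarray
    segments: List[Tuple[int, int]]
    warnings: List[str] = field(default_factory=list)

    @property
    def n_selected(self) -> int:
        return len(self.selected_residues)


def helical_fraction(ss_codes: Sequence[str], helix_code: str = HELIX_CODE) -> np.ndarray:
    """Fraction of frames in which each residue carries the α-helix code.

    ``ss_codes`` is one string per frame, one character per residue (DSSP
    one-letter codes); all strings must have equal length.
    """
    codes = list(ss_codes)
    if not codes:
        raise InputError("need at least one frame of secondary-structure codes")
    n = len(codes[0])
    if any(len(c) != n for c in codes):
        raise InputError("ragged secondary-structure input: unequal frame lengths")
    arr = np.array([list(c) for c in codes])
    return (arr == helix_code).mean(axis=0)


def contact_fraction(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    cutoff: float = 1.4,
    residue_ids_a: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Fraction of frames in which each atom (or residue) of protein a lies
    within ``cutoff`` (nm, exclusive) of any atom of protein b.

    ``coords_a``/``coords_b`` are (F, Nₐ, 3) / (F, N_b, 3) arrays over F
    frames.  If ``residue_ids_a`` maps atoms of a to residues, the atom-wise
    relative contact times are averaged per residue (all-atom mode); with one
    Cα per residue the two modes coincide.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.ndim != 3 or B.ndim != 3 or A.shape[2] != 3 or B.shape[2] != 3:
        raise InputError("coordinates must be (F, N, 3) arrays")
    if A.shape[0] != B.shape[0]:
        raise InputError("both proteins must have the same number of frames")
    if B.shape[1] == 0:
        raise InputError("partner protein has no atoms")
    F = A.shape[0]
    in_contact = np.empty((F, A.shape[1]), dtype=bool)
    for f in range(F):
        diff = A[f][:, None, :] - B[f][None, :, :]
        dmin = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff)).min(axis=1)
        in_contact[f] = dmin < cutoff
    atom_fraction = in_contact.mean(axis=0)
    if residue_ids_a is None:
        return atom_fraction
    rids = np.asarray(residue_ids_a)
    if len(rids) != A.shape[1]:
        raise InputError("residue_ids_a length must match atom count of a")
    order = pd.unique(rids)
    s = pd.Series(atom_fraction).groupby(rids, sort=False).mean()
    return s.loc[order].to_numpy()


def select_stable_contact_helix(
    profile: StabilityProfile,
    helix_cutoff: float = 0.5,
    contact_cutoff: float = 0.5,
    min_segment: int = MIN_SEGMENT,
) -> SelectionResult:
    """Intersect the two stability criteria and assemble contiguous segments.

    Residues with helical_fraction ≥ helix_cutoff AND contact_fraction ≥
    contact_cutoff are kept.  Runs broken by non-qualifying residues are
    separate segments; segments shorter than ``min_segment`` are dropped with
    a warning (a fragment fit needs at least four residues).  An empty
    selection yields an empty result with a warning, not an exception.
    """
    mask = (profile.helical_fraction >= helix_cutoff) & (
        profile.contact_fraction >= contact_cutoff
    )
    warnings: List[str] = []
    segments: List[Tuple[int, int]] = []
    keep = np.zeros_like(mask)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        warnings.append("no residue satisfies both stability criteria")
        return SelectionResult(np.array([], dtype=profile.residue_ids.dtype), [], warnings)

    # split into runs of consecutive indices
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    runs = np.split(idx, breaks + 1)
    if len(runs) > 1:
        warnings.append(
            f"selection is fragmented into {len(runs)} runs; inspect whether "
            f"only parts of a helix were selected"
        )
    for run in runs:
        first, last = profile.residue_ids[run[0]], profile.residue_ids[run[-1]]
        if len(run) < min_segment:
            warnings.append(
                f"segment {first}-{last} has {len(run)} residues "
                f"(< {min_segment}); too short for fragment fitting, dropped"
            )
            continue
        segments.append((int(first), int(last)))
        keep[run] = True
    return SelectionResult(profile.residue_ids[keep], segments, warnings)


def fraction_histogram(values: np.ndarray, bins: int = 20) -> pd.DataFrame:
    """Histogram of stability fractions on [0, 1].

    The 0.5 cutoffs are justified when this distribution is distinctly
    bimodal (mass near 0 and near 1); the diagnostic lets users verify that
    on their own data.
    """
    counts, edges = np.histogram(np.asarray(values, dtype=float), bins=bins, range=(0, 1))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def parse_dssp(path) -> Tuple[np.ndarray, str]:
    """Minimal parser for classic DSSP output: residue numbers and the
    one-letter secondary-structure column.

    Returns (residue_ids, codes) for one structure; blank codes become '-'.
    Chain breaks (residue marked '!') are skipped.
    """
    residue_ids = []
    codes = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            if line.startswith("  #  RESIDUE"):
                in_table = True
                continue
            if not in_table or len(line) < 17:
                continue
            if line[13] == "!":
                continue
            try:
                residue_ids.append(int(line[5:10]))
            except ValueError:
                continue
            ss = line[16]
            codes.append("-" if ss == " " else ss)
    if not residue_ids:
        raise InputError(f"no residue records found in DSSP file {path}")
    return np.asarray(residue_ids), "".join(codes)


def read_ss_strings(path) -> List[str]:
    """Per-frame secondary-structure strings: one line per frame."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InputError(f"no secondary-structure strings in {path}")
    return lines
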