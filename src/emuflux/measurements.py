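"""GC-MS amino-acid fragment measurement model.

Proteinogenic amino acids are hydrolyzed from biomass, TBDMS-derivatized and
measured by GC-MS; each fragment retains a known subset of the carbon
backbone of one or more precursor metabolites of central metabolism.  Two
concerns live here:

* mapping a fragment definition to the EMU(s) whose simulated MID predicts
  its backbone MID (convolved when a fragment spans several precursors), and
* the natural-isotope correction: the derivatization group contributes
  C/H/N/O/Si/S atoms whose heavy natural isotopes shift the observed mass
  distribution; the correction matrix relates the backbone MID to the
  observed one.

Fragment libraries are data (YAML), not code; the library shipped with the
package describes the synthetic networks only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import nnls

from .emu import EMU, MIDVector, convolve

__all__ = [
    "FragmentDef",
    "MeasuredMID",
    "ISOTOPE_ABUNDANCES",
    "natural_abundance_matrix",
    "correct_mid",
    "apply_correction",
    "map_fragment_to_emus",
    "load_fragment_library",
    "read_mid_table",
    "write_mid_table",
]

# Natural isotope abundances as mass-shift distributions (M+0, M+1, M+2, ...).
# Standard IUPAC terrestrial values.
ISOTOPE_ABUNDANCES: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}

DEFAULT_MID_SD = 0.003  # mass-fraction units; applied when a table has no SDs
MID_SUM_TOLERANCE = 0.02  # measured fractions may lose truncated heavy tail


@dataclass(frozen=True)
class FragmentDef:
    """One measurable fragment.

    ``precursors`` lists ``(metabolite_id, carbon_positions)`` — the backbone
    carbons retained from each precursor.  ``formula`` counts the
    *non-backbone* atoms (derivatization group plus any skeleton atoms not
    traced), whose natural isotopes must be corrected out.
    """

    id: str
    amino_acid: str
    precursors: tuple[tuple[str, tuple[int, ...]], ...]
    formula: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.formula.values()):
            raise ValueError(f"{self.id}: negative element count")
        unknown = set(self.formula) - set(ISOTOPE_ABUNDANCES)
        if unknown:
            raise ValueError(f"{self.id}: no isotope data for {sorted(unknown)}")

    @property
    def backbone_size(self) -> int:
        return sum(len(pos) for _, pos in self.precursors)


@dataclass
class MeasuredMID:
    """Observed mass fractions of one fragment with standard deviations."""

    fragment_id: str
    fractions: np.ndarray
    sd: np.ndarray
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, float)
        self.sd = np.asarray(self.sd, float)
        if self.sd.shape != self.fractions.shape:
            raise ValueError(f"{self.fragment_id}: SD shape mismatch")
        if np.any(self.fractions < -1e-9):
            raise ValueError(f"{self.fragment_id}: negative mass fraction")
        if np.any(self.sd <= 0):
            raise ValueError(f"{self.fragment_id}: SDs must be positive")
        total = self.fractions.sum()
        if abs(total - 1.0) > MID_SUM_TOLERANCE:
            raise ValueError(
                f"{self.fragment_id}: fractions sum to {total:.4f} "
                f"(tolerance {MID_SUM_TOLERANCE})")


def natural_abundance_matrix(
    fragment: FragmentDef,
    backbone_carbons: int,
    *,
    window: int | None = None,
    abundances: dict[str, tuple[float, ...]] | None = None,
) -> np.ndarray:
    """Correction matrix M with ``observed = M @ backbone_mid``.

    Column j is the natural-isotope mass-shift kernel of the non-backbone
    atoms, shifted down by j rows and truncated to the observed mass window
    (default ``backbone_carbons + 1`` channels); columns therefore sum to at
    most 1.
    """
    if window is None:
        window = backbone_carbons + 1
    table = ISOTOPE_ABUNDANCES if abundances is None else abundances
    kernel = np.ones(1)
    for element, count in sorted(fragment.formula.items()):
        dist = np.asarray(table[element], float)
        for _ in range(count):
            kernel = np.convolve(kernel, dist)
    M = np.zeros((window, backbone_carbons + 1))
    for j in range(backbone_carbons + 1):
        seg = kernel[: window - j]
        M[j: j + len(seg), j] = seg
    return M


def apply_correction(M: np.ndarray, backbone_mid: np.ndarray) -> np.ndarray:
    """Forward model: observed mass fractions from a backbone MID."""
    return M @ np.asarray(backbone_mid, float)


def correct_mid(observed: MeasuredMID, M: np.ndarray) -> MIDVector:
    """Infer the backbone MID from an observed fragment MID.

    Solves ``min ||M x - observed||`` subject to x >= 0, then renormalizes to
    sum 1.  Warns when M is ill-conditioned (cond > 1e8), which happens for
    degenerate isotope tables, not for realistic derivatization formulas.
    """
    if M.shape[0] != len(observed.fractions):
        raise ValueError(
            f"{observed.fragment_id}: matrix has {M.shape[0]} rows but "
            f"observation has {len(observed.fractions)} channels")
    if np.linalg.cond(M) > 1e8:
        warnings.warn(
            f"{observed.fragment_id}: correction matrix is ill-conditioned",
            RuntimeWarning, stacklevel=2)
    x, _ = nnls(M, np.clip(observed.fractions, 0.0, None))
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{observed.fragment_id}: correction produced a zero MID")
    return MIDVector(observed.fragment_id, x / total)


def map_fragment_to_emus(fragment: FragmentDef, network=None) -> list[EMU]:
    """EMUs whose (convolved) simulated MID predicts the fragment backbone."""
    emus = []
    for met, positions in fragment.precursors:
        if network is not None:
            if not any(m.id == met for m in network.metabolites):
                raise KeyError(
                    f"{fragment.id}: precursor {met!r} not in the network")
            if max(positions) > network.metabolite(met).n_carbons:
                raise ValueError(
                    f"{fragment.id}: position out of range for {met}")
        emus.append(EMU(met, tuple(positions)))
    return emus


def predict_fragment_mid(fragment: FragmentDef,
                         emu_mids: dict[EMU, np.ndarray]) -> np.ndarray:
    """Backbone MID of a fragment from simulated EMU MIDs (convolved if the
    fragment spans several precursor molecules)."""
    mids = [emu_mids[e] for e in map_fragment_to_emus(fragment)]
    out = mids[0]
    for m in mids[1:]:
        out = convolve(out, m)
    return out


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def load_fragment_library(path_or_text) -> dict[str, FragmentDef]:
    """Load a YAML fragment library.

    Schema: ``{fragment_id: {amino_acid, precursors: [{metabolite,
    positions}], formula: {element: count}}}``.
    """
    from pathlib import Path

    if hasattr(path_or_text, "read"):
        doc = yaml.safe_load(path_or_text)
    elif isinstance(path_or_text, Path) or (
            isinstance(path_or_text, str) and "\n" not in path_or_text
            and Path(path_or_text).exists()):
        doc = yaml.safe_load(Path(path_or_text).read_text())
    else:
        doc = yaml.safe_load(path_or_text)
    frags = {}
    for fid, entry in doc.items():
        precursors = tuple(
            (p["metabolite"], tuple(int(i) for i in p["positions"]))
            for p in entry["precursors"])
        frags[fid] = FragmentDef(
            id=fid,
            amino_acid=entry.get("amino_acid", ""),
            precursors=precursors,
            formula={k: int(v) for k, v in entry.get("formula", {}).items()},
        )
    return frags


def read_mid_table(path, default_sd: float = DEFAULT_MID_SD) -> list[MeasuredMID]:
    """Read a measured-MID CSV with columns
    ``fragment, mass_shift, fraction, sd, replicate`` (sd/replicate optional).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {"fragment", "mass_shift", "fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"MID table must have columns {sorted(required)}")
    out = []
    for fid, grp in df.groupby("fragment", sort=False):
        grp = grp.sort_values("mass_shift")
        shifts = grp["mass_shift"].to_numpy()
        if not np.array_equal(shifts, np.arange(len(shifts))):
            raise ValueError(f"{fid}: mass shifts must be 0..n without gaps")
        sd = (grp["sd"].to_numpy(float) if "sd" in grp and grp["sd"].notna().all()
              else np.full(len(grp), default_sd))
        nrep = int(grp["replicate"].max()) if "replicate" in grp else 1
        out.append(MeasuredMID(str(fid), grp["fraction"].to_numpy(float), sd, nrep))
    return out


def write_mid_table(measurements: list[MeasuredMID], path) -> None:
    import pandas as pd

    rows = []
    for m in measurements:
        for k, (frac, sd) in enumerate(zip(m.fractions, m.sd)):
            rows.append({"fragment": m.fragment_id, "mass_shift": k,
                         "fraction": frac, "sd": sd, "replicate": m.n_replicates})
    pd.DataFrame(rows).to_csv(path, index=False)
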