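"""Mean-distance substrate-likeliness calls and the species report table.

A ligand is called a likely substrate ("Yes") of a CYP when the mean
distance between its reactive atom and the heme Fe over the trajectory is
at or below a threshold, 0.53 nm by default; a strictly wider mean distance
means the atom cannot reach the iron often enough to be hydroxylated
efficiently ("No"). The call is qualitative and uses the mean only; SD and
the fraction of frames below threshold are carried as diagnostics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import pandas as pd

from .geometry import DistanceSeries, DistanceSummary, summarize

DEFAULT_THRESHOLD_NM = 0.53

__all__ = ["ClassificationResult", "classify", "species_report", "report_to_json"]


@dataclass(frozen=True)
class ClassificationResult:
    """One substrate-likeliness call: one cell of the species report."""

    complex_id: str
    molecule: str
    species: str
    cyp: str
    mean: float  # nm
    sd: float | None  # nm, None when only a bare mean was supplied
    threshold: float  # nm
    call: str  # "Yes" | "No"
    fraction_below_threshold: float | None = None
    basis: str = "calculated"

    def __post_init__(self) -> None:
        expected = "No" if self.mean > self.threshold else "Yes"
        if self.call != expected:
            raise ValueError("call inconsistent with mean/threshold")
        f = self.fraction_below_threshold
        if f is not None and not 0.0 <= f <= 1.0:
            raise ValueError("fraction_below_threshold outside [0, 1]")


def classify(
    data: DistanceSummary | DistanceSeries | float,
    threshold: float = DEFAULT_THRESHOLD_NM,
    *,
    complex_id: str = "",
    molecule: str = "",
    species: str = "",
    cyp: str = "",
) -> ClassificationResult:
    """Apply the mean-distance threshold.

    ``mean > threshold`` gives "No" (not efficiently biotransformed at the
    designated atom); a mean at or below the threshold gives "Yes". Accepts
    a full series (fraction of frames below threshold is then reported), a
    precomputed summary, or a bare mean in nm.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    fraction = None
    sd: float | None
    if isinstance(data, DistanceSeries):
        summary = summarize(data)
        mean, sd = summary.mean, summary.sd
        fraction = float((data.values <= threshold).mean())
        complex_id = complex_id or data.complex_id
    elif isinstance(data, DistanceSummary):
        mean, sd = data.mean, data.sd
    else:
        mean, sd = float(data), None
    return ClassificationResult(
        complex_id=complex_id,
        molecule=molecule,
        species=species,
        cyp=cyp,
        mean=mean,
        sd=sd,
        threshold=threshold,
        call="No" if mean > threshold else "Yes",
        fraction_below_threshold=fraction,
    )


def _column_family(cyp: str) -> str:
    """Which report column a CYP label belongs to."""
    return "CYP1A2" if "1A2" in cyp.upper() else "CYP2A6"


def species_report(results: list[ClassificationResult]) -> pd.DataFrame:
    """Arrange calls as a species table: one molecule/species row pair of
    CYP2A6-homolog and CYP1A2 columns, "n.p." where a complex was not run.

    A species with several homologs on one side (the rabbit CYP2A10/CYP2A11
    case) gets one row per homolog on that side. Row order is deterministic:
    molecule, then species alphabetically, then mean distance.
    """
    if not results:
        raise ValueError("no classification results to report")
    seen = set()
    for r in results:
        key = (r.molecule, r.species, r.cyp)
        if key in seen:
            raise ValueError(f"duplicate (molecule, species, cyp) entry: {key}")
        seen.add(key)

    groups: dict[tuple[str, str], dict[str, list[ClassificationResult]]] = {}
    for r in results:
        side = _column_family(r.cyp)
        groups.setdefault((r.molecule, r.species), {"CYP2A6": [], "CYP1A2": []})[
            side
        ].append(r)

    rows = []
    for (molecule, species) in sorted(groups):
        sides = groups[(molecule, species)]
        left = sorted(sides["CYP2A6"], key=lambda r: (r.mean, r.cyp))
        right = sorted(sides["CYP1A2"], key=lambda r: (r.mean, r.cyp))
        for k in range(max(len(left), len(right), 1)):
            lr = left[k] if k < len(left) else None
            rr = right[k] if k < len(right) else None
            rows.append(
                {
                    "molecule": molecule if k == 0 else "",
                    "species": species if k == 0 else "",
                    "cyp2a6_homolog": lr.cyp if lr else "n.p.",
                    "cyp2a6_distance_nm": _fmt_dist(lr),
                    "cyp2a6_call": f"{lr.call} ({lr.basis})" if lr else "n.p.",
                    "cyp1a2_homolog": rr.cyp if rr else "n.p.",
                    "cyp1a2_distance_nm": _fmt_dist(rr),
                    "cyp1a2_call": f"{rr.call} ({rr.basis})" if rr else "n.p.",
                }
            )
    return pd.DataFrame(rows)


def _fmt_dist(r: ClassificationResult | None) -> str:
    if r is None:
        return "n.p."
    if r.sd is None:
        return f"{r.mean:.2f}"
    return f"{r.mean:.2f} ± {r.sd:.2f}"


def report_to_json(results: list[ClassificationResult]) -> str:
    """Machine-readable companion of the species report (full precision)."""
    payload = [asdict(r) for r in sorted(results, key=lambda r: (r.molecule, r.species, r.cyp))]
    return json.dumps(payload, indent=2, sort_keys=True)
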