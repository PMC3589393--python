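"""Hydrogen/deuterium-exchange mass shifts to deuteron counts and tests.

Global HDX-MS: a protein incubated in D2O gains one DELTA_MASS_D_H per
exchanged hydrogen; the intact-protein mass shift relative to the
undeuterated reference therefore counts exchanged amides.  Deuterium
lost between quench and detection (back-exchange) is estimated from a
perdeuterated control and corrected multiplicatively.  Between-condition
differences are assessed with two-sided pooled-variance t-tests
(alpha = 0.05), matching how ligand effects on exchange are judged.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .masses import DELTA_MASS_D_H

#: fraction of amide hydrogens assumed exchanged in the perdeuterated control
PERDEUTERATION_FRACTION = 0.90
ALPHA = 0.05


@dataclass
class HdxRecord:
    """Replicate observed masses for one condition and D2O exposure time."""

    condition: str
    time_in_D2O: float  # minutes
    replicate_masses: np.ndarray
    reference_mass_H: float
    perdeuterated_mass_obs: float | None = None

    def __post_init__(self) -> None:
        self.replicate_masses = np.asarray(self.replicate_masses, dtype=float)
        if self.replicate_masses.size < 1:
            raise ValueError("need at least one replicate mass")
        if not self.time_in_D2O > 0:
            raise ValueError("exposure time must be positive")
        if not self.reference_mass_H > 0:
            raise ValueError("reference mass must be positive")
        if np.any(self.replicate_masses <= self.reference_mass_H - 1.0):
            raise ValueError("replicate masses fall below the reference mass")


def deuteron_count(observed_mass: float, reference_mass_h: float) -> float:
    """Deuterons incorporated: (observed - reference) / (m2H - m1H).

    The reference is the undeuterated protein in H2O.  Because only a
    mass *difference* enters, average and monoisotopic mass conventions
    cancel.  Slightly negative differences (noise) clip to 0.
    """
    if observed_mass <= 0 or reference_mass_h <= 0:
        raise ValueError("masses must be positive")
    count = (observed_mass - reference_mass_h) / DELTA_MASS_D_H
    if count < 0:
        warnings.warn("observed mass below reference; clipping count to 0")
        return 0.0
    return count


def back_exchange_fraction(
    perdeut_obs: float,
    reference_mass_h: float,
    n_amides: int,
    fraction_exchanged: float = PERDEUTERATION_FRACTION,
) -> float:
    """Back-exchange estimated from a perdeuterated control.

    theory = reference + fraction_exchanged * n_amides * (m2H - m1H);
    the fraction of incorporated deuterium lost before detection is
    (theory - observed) / (theory - reference), clamped to [0, 1).
    """
    if n_amides <= 0:
        raise ValueError("n_amides must be positive")
    if perdeut_obs < reference_mass_h:
        raise ValueError("perdeuterated mass below the reference mass")
    theory = reference_mass_h + fraction_exchanged * n_amides * DELTA_MASS_D_H
    if perdeut_obs > theory:
        warnings.warn("perdeuterated control above theoretical mass; "
                      "back-exchange set to 0")
        return 0.0
    frac = (theory - perdeut_obs) / (theory - reference_mass_h)
    return min(max(frac, 0.0), 1.0 - 1e-12)


def correct_deuterons(raw_count: float, back_exchange: float) -> float:
    """Back-exchange-corrected count, raw / (1 - back_exchange)."""
    if not 0.0 <= back_exchange < 1.0:
        raise ValueError("back-exchange fraction must lie in [0, 1)")
    return raw_count / (1.0 - back_exchange)


def ttest_unpaired(a, b) -> tuple[float, int, float]:
    """Two-sided pooled-variance Student's t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    df = len(a) + len(b) - 2
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        # degenerate: no within-group scatter
        if np.mean(a) == np.mean(b):
            return 0.0, df, 1.0
        warnings.warn("zero pooled variance with unequal means; p -> 0")
        return np.inf, df, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), df, float(p)


def amide_count(sequence: str) -> int:
    """Exchangeable backbone amides: residues - 1 (N-terminus) - prolines."""
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty sequence")
    return len(seq) - 1 - seq.count("P")


def amide_count_from_fasta(path) -> int:
    """Amide count for the first record of a FASTA file."""
    from Bio import SeqIO
    try:
        record = next(SeqIO.parse(str(path), "fasta"))
    except StopIteration:
        raise ValueError(f"no FASTA records in {path}") from None
    return amide_count(str(record.seq))


def summarize_conditions(
    records: list[HdxRecord],
    back_exchange: float | None = None,
    n_amides: int | None = None,
    apo_condition: str = "apo",
    control_condition: str = "SA-OH",
) -> pd.DataFrame:
    """Per-condition deuteron counts with SEMs and pairwise t-tests.

    When ``back_exchange`` is None it is estimated per record from the
    perdeuterated control (requires ``n_amides``).  The returned frame
    has one row per (condition, time) with raw and corrected mean +/-
    SEM, p-values against the apo and benzenesulfonamide-only controls,
    and significance stars ('*' vs apo, '**' vs control, p < 0.05)
    following the usual figure convention.
    """
    if not records:
        raise ValueError("no records")
    counts: dict[tuple[str, float], np.ndarray] = {}
    bx: dict[tuple[str, float], float] = {}
    for rec in records:
        key = (rec.condition, rec.time_in_D2O)
        counts[key] = np.array([
            deuteron_count(m, rec.reference_mass_H)
            for m in rec.replicate_masses
        ])
        if back_exchange is not None:
            bx[key] = back_exchange
        elif rec.perdeuterated_mass_obs is not None and n_amides:
            bx[key] = back_exchange_fraction(
                rec.perdeuterated_mass_obs, rec.reference_mass_H, n_amides)
        else:
            bx[key] = 0.0

    times = sorted({t for _, t in counts})
    have_apo = any(c == apo_condition for c, _ in counts)
    if not have_apo:
        warnings.warn("no apo condition present; comparisons vs apo omitted")

    rows = []
    for time in times:
        keys = [k for k in counts if k[1] == time]
        for cond, t in keys:
            vals = counts[(cond, t)]
            mean = float(np.mean(vals))
            sem = (float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                   if len(vals) > 1 else 0.0)
            frac = bx[(cond, t)]
            row = {
                "condition": cond,
                "time_min": t,
                "n_replicates": len(vals),
                "mean_deuterons": mean,
                "sem_deuterons": sem,
                "back_exchange_fraction": frac,
                "corrected_deuterons": correct_deuterons(mean, frac),
                "corrected_sem": correct_deuterons(sem, frac),
                "p_vs_apo": np.nan,
                "p_vs_control": np.nan,
                "significance": "",
            }
            for other, col in ((apo_condition, "p_vs_apo"),
                               (control_condition, "p_vs_control")):
                if cond != other and (other, t) in counts \
                        and len(vals) > 1 and len(counts[(other, t)]) > 1:
                    _, _, p = ttest_unpaired(vals, counts[(other, t)])
                    row[col] = p
            stars = ""
            if np.isfinite(row["p_vs_apo"]) and row["p_vs_apo"] < ALPHA:
                stars += "*"
            if np.isfinite(row["p_vs_control"]) and row["p_vs_control"] < ALPHA:
                stars += "**"
            row["significance"] = stars
            rows.append(row)
    frame = pd.DataFrame(rows).sort_values(["time_min", "condition"])
    return frame.reset_index(drop=True)


def pairwise_pvalues(
    records: list[HdxRecord], time: float
) -> pd.DataFrame:
    """Full matrix of pooled-variance p-values among conditions at one time."""
    groups = {
        rec.condition: np.array([
            deuteron_count(m, rec.reference_mass_H)
            for m in rec.replicate_masses])
        for rec in records if rec.time_in_D2O == time
    }
    conds = sorted(groups)
    mat = pd.DataFrame(np.nan, index=conds, columns=conds)
    for a, b in itertools.combinations(conds, 2):
        if len(groups[a]) > 1 and len(groups[b]) > 1:
            _, _, p = ttest_unpaired(groups[a], groups[b])
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat
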