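"""Receptor specialization, pleiotropy, and hybrid-incompatibility geometry.

Each genotype's fitness on the two receptors comes from the single-host
landscapes: ``S_L`` (LamB fitness) from the LamB-only environment E and
``S_O`` (OmpF fitness) from the OmpF-only environment A.  The
specialization index contrasts the exponentiated rates (which are
proportional to plaque-forming units)::

    SI = (e^{S_L} - e^{S_O}) / (e^{S_L} + e^{S_O})  =  tanh((S_L - S_O)/2)

ranging from -1 (complete OmpF specialist) to +1 (complete LamB
specialist); EvoC sits at 0 by construction.  A genotype is called a
specialist when |SI| strictly exceeds 0.33, the value at which growth on
the preferred receptor is about twofold (or more) that on the other.

Hybrid incompatibility is assessed geometrically in the (S_O, S_L) plane:
for a pair of opposing specialists, the in-silico hybrid carries the union
of both parents' mutations, and its signed perpendicular displacement from
the line connecting the parents (positive toward higher S_O + S_L)
measures whether hybridization improved or worsened average receptor
fitness.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    N_GENOTYPES,
    N_SITES,
    FitnessLandscape,
    ValidationError,
    all_genotypes,
    genotype_from_index,
)

PHENOTYPE_CLASSES = ("L_specialist", "O_specialist", "generalist", "undefined")
DEFAULT_SI_THRESHOLD = 0.33


def specialization_index(s_l, s_o):
    """SI from the two receptor selection rates (NaN if either missing).

    Computed as tanh((S_L - S_O)/2), the numerically stable form of the
    difference-over-sum of exponentiated rates; antisymmetric in its
    arguments and bounded in [-1, 1].
    """
    s_l = np.asarray(s_l, dtype=float)
    s_o = np.asarray(s_o, dtype=float)
    out = np.tanh((s_l - s_o) / 2.0)
    if out.ndim == 0:
        return float(out)
    return out


def classify_phenotype(si, threshold: float = DEFAULT_SI_THRESHOLD):
    """Specialist/generalist class from SI; strict inequality at the cutoff."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie strictly between 0 and 1")
    si = np.asarray(si, dtype=float)
    out = np.where(
        np.isnan(si),
        "undefined",
        np.where(
            si > threshold,
            "L_specialist",
            np.where(si < -threshold, "O_specialist", "generalist"),
        ),
    )
    if out.ndim == 0:
        return str(out)
    return out


def phenotype_table(
    landscape_a: FitnessLandscape,
    landscape_e: FitnessLandscape,
    threshold: float = DEFAULT_SI_THRESHOLD,
) -> pd.DataFrame:
    """Per-genotype S_L, S_O, SI and phenotype class for the whole library."""
    s_o = landscape_a.values  # environment A: OmpF-only hosts
    s_l = landscape_e.values  # environment E: LamB-only hosts
    si = specialization_index(s_l, s_o)
    return pd.DataFrame(
        {
            "genotype": all_genotypes(),
            "S_L": s_l,
            "S_O": s_o,
            "SI": si,
            "phenotype_class": classify_phenotype(si, threshold),
        }
    )


def mutation_effect_distributions(
    landscape_a: FitnessLandscape, landscape_e: FitnessLandscape
) -> tuple[pd.DataFrame, dict]:
    """Fitness change of adding each mutation to every background.

    For each genotype ``g`` lacking site ``i``, the rows hold
    ``delta_S_O = S_A(g+i) - S_A(g)`` and ``delta_S_L = S_E(g+i) - S_E(g)``
    (NaN where either endpoint is unobserved on that receptor).  The
    summary reports the median change per receptor and the number of
    background/mutation pairs skipped for missing data.
    """
    s_o = landscape_a.values
    s_l = landscape_e.values
    rows = []
    for site in range(N_SITES):
        bit = 1 << site
        backgrounds = np.array(
            [g for g in range(N_GENOTYPES) if not g & bit], dtype=np.int64
        )
        partners = backgrounds | bit
        d_o = s_o[partners] - s_o[backgrounds]
        d_l = s_l[partners] - s_l[backgrounds]
        for g, do, dl in zip(backgrounds, d_o, d_l):
            if np.isnan(do) and np.isnan(dl):
                continue
            rows.append((genotype_from_index(int(g)), site + 1, do, dl))
    frame = pd.DataFrame(
        rows, columns=["background", "site", "delta_S_O", "delta_S_L"]
    )
    n_total = N_SITES * N_GENOTYPES // 2
    summary = {
        "median_delta_S_O": float(np.nanmedian(frame["delta_S_O"])) if len(frame) else np.nan,
        "median_delta_S_L": float(np.nanmedian(frame["delta_S_L"])) if len(frame) else np.nan,
        "n_pairs_O": int(frame["delta_S_O"].notna().sum()),
        "n_pairs_L": int(frame["delta_S_L"].notna().sum()),
        "skipped_O": n_total - int(frame["delta_S_O"].notna().sum()),
        "skipped_L": n_total - int(frame["delta_S_L"].notna().sum()),
    }
    return frame, summary


def select_specialists(
    records: pd.DataFrame,
    threshold: float = DEFAULT_SI_THRESHOLD,
    k: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Specialist panels for the hybrid analysis.

    Only genotypes with observed rates on both receptors are eligible.  The
    L panel holds every eligible genotype with SI strictly above the
    threshold (capped at the ``k`` most specialized if given); the O panel
    holds the equally many most-specialized (most negative SI) eligible
    genotypes below ``-threshold``.
    """
    observed = records[np.isfinite(records["S_L"]) & np.isfinite(records["S_O"])]
    l_panel = observed[observed["SI"] > threshold].sort_values("SI", ascending=False)
    if k is not None:
        l_panel = l_panel.head(k)
    o_candidates = observed[observed["SI"] < -threshold].sort_values("SI")
    if len(o_candidates) < len(l_panel):
        warnings.warn(
            f"only {len(o_candidates)} O-specialist candidates for "
            f"{len(l_panel)} L-specialists; truncating",
            stacklevel=2,
        )
    o_panel = o_candidates.head(len(l_panel))
    return l_panel.reset_index(drop=True), o_panel.reset_index(drop=True)


def hybrid_displacement(
    parent_l: Sequence[float],
    parent_o: Sequence[float],
    hybrid: Sequence[float],
    exponentiate: bool = False,
) -> float:
    """Signed perpendicular distance from the parent line to the hybrid.

    Points are (S_O, S_L) coordinates; with ``exponentiate`` the analysis
    runs on (e^{S_O}, e^{S_L}) instead.  Positive values point toward
    increasing S_O + S_L, i.e. improved average receptor fitness.
    """
    p1 = np.asarray(parent_l, dtype=float)
    p2 = np.asarray(parent_o, dtype=float)
    h = np.asarray(hybrid, dtype=float)
    if exponentiate:
        p1, p2, h = np.exp(p1), np.exp(p2), np.exp(h)
    direction = p2 - p1
    norm = np.hypot(*direction)
    if norm == 0:
        raise ValidationError("parent points coincide; displacement undefined")
    normal = np.array([-direction[1], direction[0]]) / norm
    if normal.sum() < 0:  # orient toward increasing S_O + S_L
        normal = -normal
    return float(normal @ (h - p1))


def hybrid_analysis(
    records: pd.DataFrame,
    threshold: float = DEFAULT_SI_THRESHOLD,
    k: int | None = None,
    exponentiate: bool = False,
) -> tuple[pd.DataFrame, float]:
    """All specialist x specialist hybrid trios and the fraction below.

    Every L-panel x O-panel pair yields the hybrid carrying the union of
    the parents' mutations.  A trio is invalid when the hybrid equals a
    parent or lacks an observed rate on either receptor; ``fraction_below``
    is the share of valid trios whose displacement is strictly negative.
    """
    l_panel, o_panel = select_specialists(records, threshold, k)
    by_genotype = records.set_index("genotype")
    rows = []
    for _, l_row in l_panel.iterrows():
        l_bits = int(l_row["genotype"][::-1], 2)
        for _, o_row in o_panel.iterrows():
            o_bits = int(o_row["genotype"][::-1], 2)
            hybrid_key = genotype_from_index(l_bits | o_bits)
            valid = hybrid_key not in (l_row["genotype"], o_row["genotype"])
            displacement = np.nan
            if valid:
                h = by_genotype.loc[hybrid_key]
                if np.isfinite(h["S_O"]) and np.isfinite(h["S_L"]):
                    displacement = hybrid_displacement(
                        (l_row["S_O"], l_row["S_L"]),
                        (o_row["S_O"], o_row["S_L"]),
                        (h["S_O"], h["S_L"]),
                        exponentiate=exponentiate,
                    )
                else:
                    valid = False
            rows.append(
                (l_row["genotype"], o_row["genotype"], hybrid_key, displacement, valid)
            )
    trios = pd.DataFrame(
        rows, columns=["parent_L", "parent_O", "hybrid", "displacement", "valid"]
    )
    valid_disp = trios.loc[trios["valid"], "displacement"]
    fraction_below = float((valid_disp < 0).mean()) if len(valid_disp) else np.nan
    return trios, fraction_below
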