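"""Combine the evidence streams into a ranked hinge-candidate report.

Evidence tiers:
  A — multimodal AND state-shifted AND tally-significant,
  B — multimodal AND (state-shifted OR tally-significant),
  C — multimodal only,
  "" — everything else.
Adding evidence can only raise a residue's tier. Candidate selection applies
a conservation rule on top; because the published identity-only rule does not
arithmetically reproduce the published mutant list (a 31%-identity residue
was mutated), both the identity-only and the combined (identity +
conservative) rule are first-class and reports carry both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .conservation import flag_conserved

_TIER_ORDER = {"A": 3, "B": 2, "C": 1, "": 0}


def _tier(multimodal: bool, shifted: bool, significant: bool) -> str:
    if not multimodal:
        return ""
    if shifted and significant:
        return "A"
    if shifted or significant:
        return "B"
    return "C"


@dataclass
class HingeReport:
    table: pd.DataFrame  # one row per residue
    parameters: dict = field(default_factory=dict)

    def residues_in_tier(self, tier: str) -> set[int]:
        return set(self.table.loc[self.table["tier"] == tier, "residue"].astype(int))

    def row(self, residue: int) -> pd.Series:
        sub = self.table.loc[self.table["residue"] == residue]
        if len(sub) == 0:
            raise KeyError(f"residue {residue} not in report")
        return sub.iloc[0]


def build_report(
    universe: Sequence[int],
    multimodal: set[int],
    shifted: Mapping[int, bool] | set[int],
    tally_counts: Mapping[int, int],
    min_runs: int = 4,
    conservation_profile: pd.DataFrame | None = None,
    distances: pd.DataFrame | None = None,
    identity_min: float = 90.0,
    groups_required: tuple[str, ...] = ("bacteria", "animals"),
    parameters: Mapping | None = None,
) -> HingeReport:
    """Per-residue evidence table over a common residue universe."""
    universe = sorted(set(int(r) for r in universe))
    bad = [r for r in multimodal if r not in universe]
    if bad:
        raise ValueError(f"multimodal residues outside the universe: {bad[:5]}")
    if isinstance(shifted, set) or isinstance(shifted, frozenset):
        shifted = {r: True for r in shifted}
    conserved_id: set[int] = set()
    conserved_comb: set[int] = set()
    if conservation_profile is not None:
        conserved_id = flag_conserved(
            conservation_profile, identity_min, groups_required, mode="identity"
        )
        conserved_comb = flag_conserved(
            conservation_profile, identity_min, groups_required, mode="combined"
        )
    dist_map = {}
    if distances is not None:
        dist_map = {
            int(r["residue"]): (float(r["min_distance"]), bool(r["near"]))
            for _, r in distances.iterrows()
        }
    rows = []
    for r in universe:
        is_mm = r in multimodal
        is_sh = bool(shifted.get(r, False))
        count = int(tally_counts.get(r, 0))
        sig = count >= min_runs
        d, near = dist_map.get(r, (float("nan"), False))
        rows.append(
            {
                "residue": r,
                "multimodal": is_mm,
                "state_shifted": is_sh,
                "tally_count": count,
                "tally_significant": sig,
                "conserved_identity": r in conserved_id,
                "conserved_combined": r in conserved_comb,
                "ligand_distance": d,
                "near_ligand": near,
                "tier": _tier(is_mm, is_sh, sig),
            }
        )
    params = dict(parameters or {})
    params.setdefault("min_runs", min_runs)
    params.setdefault("identity_min", identity_min)
    params.setdefault("groups_required", list(groups_required))
    params["conservation_evaluated"] = conservation_profile is not None
    return HingeReport(table=pd.DataFrame(rows), parameters=params)


def select_candidates(
    report: HingeReport,
    rule: str = "combined90",
    require_multimodal: bool = True,
) -> list[int]:
    """Residues passing the conservation rule (and multimodality), sorted by
    tier then residue number.

    Rules: ``"combined90"`` (identity + conservative >= threshold in every
    required group), ``"identity90"`` (identity only), ``"none"`` (tiered
    evidence only — used when conservation was not evaluated).
    """
    t = report.table
    if rule == "none" or not report.parameters.get("conservation_evaluated", False):
        mask = t["tier"] != ""
        rule_text = "tier-based only (conservation not evaluated)"
    elif rule == "combined90":
        mask = t["conserved_combined"]
        rule_text = "identity + conservative >= threshold in all required groups"
    elif rule == "identity90":
        mask = t["conserved_identity"]
        rule_text = "identity >= threshold in all required groups"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    if require_multimodal:
        mask = mask & t["multimodal"]
    sub = t.loc[mask].copy()
    sub["tier_rank"] = sub["tier"].map(_TIER_ORDER)
    sub = sub.sort_values(["tier_rank", "residue"], ascending=[False, True])
    report.parameters["selection_rule"] = rule
    report.parameters["selection_rule_text"] = rule_text
    return [int(r) for r in sub["residue"]]


def group_candidates(report: HingeReport, candidates: Sequence[int]) -> dict[str, set[int]]:
    """Split candidates by nucleotide-correlation tally significance."""
    universe = set(report.table["residue"].astype(int))
    bad = [r for r in candidates if r not in universe]
    if bad:
        raise ValueError(f"candidates outside report universe: {bad[:5]}")
    sig = set(
        report.table.loc[report.table["tally_significant"], "residue"].astype(int)
    )
    cset = set(int(r) for r in candidates)
    return {"correlated": cset & sig, "uncorrelated": cset - sig}
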