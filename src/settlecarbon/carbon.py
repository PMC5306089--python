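"""Carbon-stock bookkeeping over reconciled fragments.

Each fragment carries the vegetation class of the *original* cover at its
location, so a deforested fragment contributes the density of the vegetation
that stood there.  Three totals are kept per settlement:

* ``lost``      — carbon in cleared fragments (annual deforestation + savanna
                  clearing, including reclassified hydro-over-clearing),
* ``remaining`` — carbon in forest, non-forest and cloud fragments,
* ``premodern`` — lost + remaining: the stock before modern clearing
                  (conserved exactly, same densities on both sides).

Water and excluded fragments contribute zero carbon.
"""

from __future__ import annotations

import pandas as pd

from .geodata import CarbonClassTable
from .reconcile import CLEARED_CLASSES, REMAINING_CLASSES, FinalClass

_ZERO_CARBON = {FinalClass.WATER.value, FinalClass.EXCLUDED_URBAN.value,
                FinalClass.EXCLUDED_HYDRO.value}


def attach_density(fragments: pd.DataFrame, table: CarbonClassTable) -> pd.DataFrame:
    """Add a ``density_MgC_per_ha`` column by carbon-class lookup.

    Water/excluded fragments get density 0 regardless of class; a fragment
    with an unknown class id raises ``KeyError`` naming the id.
    """
    lut = dict(zip(table.table["class_id"], table.table["carbon_density_MgC_per_ha"]))
    densities = []
    for _, f in fragments.iterrows():
        if f["final_class"] in _ZERO_CARBON:
            densities.append(0.0)
            continue
        cc = f["carbon_class"]
        if cc is None or (isinstance(cc, float) and pd.isna(cc)):
            densities.append(0.0)
            continue
        if cc not in lut:
            raise KeyError(f"unknown carbon class id {cc!r}")
        densities.append(float(lut[cc]))
    out = fragments.copy()
    out["density_MgC_per_ha"] = densities
    return out


def settlement_accounts(fragments: pd.DataFrame) -> pd.DataFrame:
    """Per-settlement area-by-class and carbon triple.

    ``fragments`` must carry ``density_MgC_per_ha``.  Returns one row per
    settlement with ``area_<CLASS>_ha`` columns, the carbon triple and the
    remaining-carbon split by class.
    """
    cleared = {c.value for c in CLEARED_CLASSES}
    remaining = {c.value for c in REMAINING_CLASSES}
    rows = []
    for sid, grp in fragments.groupby("settlement_id", sort=True):
        rec: dict = {"settlement_id": sid}
        carbon = grp["area_ha"] * grp["density_MgC_per_ha"]
        for fc in FinalClass:
            rec[f"area_{fc.value}_ha"] = float(
                grp.loc[grp["final_class"] == fc.value, "area_ha"].sum()
            )
        # reclassified hydro-over-clearing is reported with the savanna total
        reclass = grp["reclassified"].fillna(False).astype(bool)
        rec["area_reclassified_ha"] = float(grp.loc[reclass, "area_ha"].sum())
        rec["lost_MgC"] = float(carbon[grp["final_class"].isin(cleared)].sum())
        rec["remaining_MgC"] = float(carbon[grp["final_class"].isin(remaining)].sum())
        rec["premodern_MgC"] = rec["lost_MgC"] + rec["remaining_MgC"]
        for fc in REMAINING_CLASSES:
            rec[f"remaining_{fc.value}_MgC"] = float(
                carbon[grp["final_class"] == fc.value].sum()
            )
        rec["lost_DEF_PRODES_MgC"] = float(
            carbon[(grp["final_class"] == FinalClass.DEF_PRODES.value) & ~reclass].sum()
        )
        rec["lost_CLEAR_PMDBBS_MgC"] = float(
            carbon[(grp["final_class"] == FinalClass.CLEAR_PMDBBS.value) | reclass].sum()
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_accounts(accounts: pd.DataFrame, by: str | list[str] | None = None) -> pd.DataFrame:
    """Component-wise sums of settlement accounts.

    ``by`` may name grouping column(s) already present in ``accounts``
    (e.g. ``category`` or ``state`` after a registry join); ``None``
    aggregates everything into a single ``total`` row.
    """
    if accounts.empty:
        raise ValueError("aggregate_accounts needs at least one account")
    num = [c for c in accounts.columns
           if c.startswith(("area_", "lost", "remaining", "premodern"))]
    if by is None:
        out = accounts[num].sum().to_frame().T
        out.insert(0, "key", "total")
        return out
    return accounts.groupby(by, sort=True)[num].sum().reset_index()
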