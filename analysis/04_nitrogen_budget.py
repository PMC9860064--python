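"""Nitrogen budgets and synergy fold-change calls.

Writes results/budgets.csv (per culture-day N biomass, umol N/L) and
results/synergy.csv (same-strain log2FC calls); prints the day-60 carrying
capacity contrast and the synergy call table.
"""

import importlib

common = importlib.import_module("00_common")

from cocultx.nitrogen_budget import QuotaTable, budget_table, synergy_table


def main() -> None:
    expset = common.load_simulated()
    budgets = budget_table(expset.counts, expset.metadata, QuotaTable())
    budgets.to_csv(common.RESULTS / "budgets.csv", index=False)
    synergy = synergy_table(budgets)
    synergy.to_csv(common.RESULTS / "synergy.csv", index=False)

    b60 = budgets[budgets["day"] == 60.0]
    for treat, grp in b60.groupby("treatment"):
        print(f"day 60 {treat:<11} total N biomass "
              f"{grp['total_biomass'].mean():6.2f} +/- {grp['total_biomass'].std():5.2f} umol/L"
              f"  (fraction in heterotroph {100 * grp['fraction_alt'].mean():.0f}%)")
    print(f"feasible vs 100 umol N/L available: {budgets['feasible'].all()}")
    s60 = synergy[(synergy["day"] == 60.0) & (synergy["direction"] == "pro_on_alt")]
    print("day-60 heterotroph benefit (log2FC vs axenic control) by phototroph partner:")
    print(s60.groupby("pro_strain")[["log2fc"]].mean().round(2).to_string())
    print("calls:", synergy["call"].value_counts().to_dict())


if __name__ == "__main__":
    main()
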