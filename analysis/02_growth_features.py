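"""Extract growth-phase parameters and compare them across strains.

Writes results/features.csv (mu, lag, peak, r2 per culture) and prints the
one-way ANOVA of growth rate across phototroph strains with
Bonferroni-corrected pairwise tests.
"""

import importlib

common = importlib.import_module("00_common")

from cocultx.growth_features import compare_groups, extract_features


def main() -> None:
    expset = common.load_simulated()
    feats = extract_features(expset.curves)
    out = common.RESULTS / "features.csv"
    feats.to_csv(out, index=False)
    ok = feats[feats["status"] == "ok"].merge(
        expset.metadata_frame(), on="culture_id"
    )
    print(f"fitted {len(ok)}/{len(feats)} cultures (r2 > 0.9); wrote {out}")
    pro = ok[ok["pro_strain"] != "none"]
    res = compare_groups(pro["mu"], pro["pro_strain"])
    print(f"growth rate by phototroph strain: F = {res['anova']['F']:.2f}, "
          f"p = {res['anova']['p']:.3g}")
    print(res["pairwise"].to_string(index=False))


if __name__ == "__main__":
    main()
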