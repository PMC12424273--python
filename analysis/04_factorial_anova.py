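#!/usr/bin/env python
"""2x2 factorial inference on the per-tank niche components.

Fits competition x predation models to 1-WIC/TNW, WIC, BIC and TNW for
both niche kinds (diet BIC on the log scale), applying the
interaction-gated Type III / Type II flow, and runs Tukey HSD
comparisons where any term is significant. Writes an effects summary
shaped like a familiar term x (F, p) results table.
"""

from pathlib import Path

import pandas as pd

from nichevar.factorial import (
    anova_report,
    fit_2x2,
    residual_diagnostics,
    tukey_pairwise,
)
from nichevar.resource_data import ExperimentDesign, ValidationError

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
RESPONSES = ("is_index", "wic", "bic", "tnw")


def main() -> None:
    design = ExperimentDesign.read_csv(
        ROOT / "data" / "synthetic" / "design.csv"
    )
    summary = []
    for kind in ("diet", "habitat"):
        components = pd.read_csv(
            RESULTS / f"components_{kind}.csv", index_col="tank_id"
        )
        for resp in RESPONSES:
            series = components[resp]
            transform = "log" if (kind, resp) == ("diet", "bic") else "none"
            if transform == "log" and (series <= 0).any():
                transform = "none"
            try:
                fit = fit_2x2(series, design, transform=transform,
                              response_name=resp)
                table = anova_report(fit)
            except ValidationError as err:
                print(f"{kind}/{resp}: skipped ({err})")
                continue
            table.to_csv(RESULTS / f"anova_{kind}_{resp}.csv")
            diag = residual_diagnostics(fit)
            flag_note = f" flags={diag['flags']}" if diag["flags"] else ""
            row = {
                "niche_kind": kind, "response": resp, "transform": transform,
            }
            for term, short in [
                ("competition", "comp"), ("predation", "pred"),
                ("competition:predation", "inter"),
            ]:
                row[f"{short}_f"] = table.loc[term, "f"]
                row[f"{short}_p"] = table.loc[term, "p"]
                row[f"{short}_eta_sq"] = table.loc[term, "partial_eta_sq"]
            summary.append(row)
            sig_terms = table.index[:3][table["p"].iloc[:3] < 0.05].tolist()
            if sig_terms:
                posthoc = tukey_pairwise(fit)
                posthoc.to_csv(
                    RESULTS / f"posthoc_{kind}_{resp}.csv", index=False
                )
                letters = posthoc.attrs["letters"]
                print(
                    f"{kind}/{resp}: significant {sig_terms}; "
                    f"Tukey letters {letters}{flag_note}"
                )
            else:
                print(f"{kind}/{resp}: no significant terms{flag_note}")
    pd.DataFrame(summary).to_csv(RESULTS / "effects_summary.csv", index=False)
    print(f"\nwrote {RESULTS / 'effects_summary.csv'}")


if __name__ == "__main__":
    main()
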