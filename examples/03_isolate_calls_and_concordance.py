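"""Gate isolate identifications and measure concordance with a second method.

Applies the depth (>= 10 reads) and purity (>= 90% of reads on one
species) gates to annotated isolate profiles, then compares the passing
calls against an orthogonal identification (e.g. MALDI-TOF) via PPV,
Cramér's V and Theil's U.
"""

import nano16s as n16

# profiles as they would come out of annotate_sample for four isolates
profiles = {
    "iso1": n16.AbundanceProfile("iso1", {"Ec": (0.97, 194.0), "Ef": (0.03, 6.0)}, 200),
    "iso2": n16.AbundanceProfile("iso2", {"Ef": (0.95, 114.0), "Ec": (0.05, 6.0)}, 120),
    "iso3": n16.AbundanceProfile("iso3", {"Sa": (0.80, 40.0), "Se": (0.20, 10.0)}, 50),  # impure
    "iso4": n16.AbundanceProfile("iso4", {"Lg": (1.0, 8.0)}, 8),  # too shallow
}
reference_calls = {"iso1": "Ec", "iso2": "Ef", "iso3": "Sa", "iso4": "Lg"}

passing = {}
for sid, prof in profiles.items():
    call = n16.call_sample(prof)
    verdict = "pass" if call.passes_depth and call.passes_purity else "fail"
    print(f"{sid}: top={call.top_species} purity={call.purity:.2f} reads={call.n_reads} -> {verdict}")
    if verdict == "pass":
        passing[sid] = call.top_species

tp = sum(passing[s] == reference_calls[s] for s in passing)
fp = len(passing) - tp
print(f"\nPPV over passing samples: {n16.ppv(tp, fp):.2f} ({tp} concordant, {fp} discordant)")

# concordance statistics need a larger cross-tabulation to be meaningful
pairs = [("Ec", "Ec")] * 20 + [("Ef", "Ef")] * 14 + [("Sa", "Sa")] * 5 + [("Ec", "Ef")]
table = n16.ContingencyTable.from_pairs(pairs)
print(f"Cramér's V = {n16.cramers_v(table):.3f} (1 = perfect association)")
print(f"Theil's U (row|col) = {n16.theils_u(table):.3f} (entropy explained by the reference)")
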