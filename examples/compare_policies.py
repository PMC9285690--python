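"""Simulate fixed and rule-based policies under synchronous recruitment
variability and compare fishery value and pelican outcomes.

Each policy is run for 50 years; the table reports the net present value
of fishing profits (currency units; open-access profits are identically
zero by the entry/exit closure) and the long-run Brown Pelican index
(mean over the final recruitment cycle; 100 = unfished constant-forcing
equilibrium)."""

import pandas as pd

import forageweb as fw
from forageweb.ecology import simulate
from forageweb.policies import PolicyPath, get_policy
from forageweb.metrics import longrun_level, longrun_pelican_gain

sc = fw.make_scenario("OA_all", "synchronous", T=50)
period = sc.params.sardine.p

policies = {
    "open access (all)": PolicyPath.open_access(),
    "moratorium (all)": PolicyPath.moratorium(),
    "sardine HCR": get_policy("HCR"),
    "sardine hockey-stick": get_policy("hockey_stick"),
}

runs = {name: simulate(sc.params, pol, T=50) for name, pol in policies.items()}
oa = runs["open access (all)"]

rows = []
for name, tr in runs.items():
    _, J = fw.npv(tr, sc.params)
    rows.append({
        "policy": name,
        "NPV": round(J),
        "longrun_Nbp": round(longrun_level(tr, "Nbp", period), 1),
        "pelican_gain_vs_OA_%": round(longrun_pelican_gain(tr, oa, period), 1),
    })
print(pd.DataFrame(rows).to_string(index=False))
print("\nPelican gains are percent changes in the long-run index relative "
      "to all-species open access;\nthe sardine rules keep anchovy and "
      "halibut under open access (the status-quo comparison).")
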