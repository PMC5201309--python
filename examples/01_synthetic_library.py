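"""Generate a synthetic aligned inhibitor series and inspect its activities.

The generator emulates a congeneric series after alignment: rigid molecules
sharing a hydrophobic core, with H-bond donor/acceptor feature pairs whose
mutual distances carry the activity signal. IC50 spans the configured range
and log(1/IC50) is linear in the planted pattern indicators plus noise.
"""

from grindqsar.synthetic import GeneratorConfig, generate_library

cfg = GeneratorConfig(n_molecules=20, seed=1)
molecules, activity = generate_library(cfg)

print(activity.head(8).to_string(index=False))
print()
print(f"{len(molecules)} molecules; IC50 range "
      f"{activity.ic50_um.min():.3f}–{activity.ic50_um.max():.1f} μM")
print("Molecules carrying a planted pattern are systematically more potent:")
print(activity.groupby(["has_OO_pattern", "has_N1N1_pattern"])
      ["log_inv_ic50"].mean().round(2).to_string())
# Each extra pattern adds ~1 log unit of potency (the generating β).
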