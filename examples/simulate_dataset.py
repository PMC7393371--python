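"""Write a complete synthetic dataset to disk in the package's file formats.

Produces the three input files every analysis stage consumes: a pair event
log (CSV), a drop event log plus exclusion metadata (CSV), and a TPS
landmark file — the same artifacts the `macromate simulate` CLI command
writes.  Re-running with the same seed reproduces the files byte for byte.
"""

from pathlib import Path

from macromate import (
    SimulationParams,
    gen_drops,
    gen_pair_logs,
    gen_stylets,
    write_event_log,
    write_tps,
)

out = Path("scratch/example_dataset")
out.mkdir(parents=True, exist_ok=True)

params = SimulationParams(seed=0)

pairs = []
for pairing_type in ("lignano", "hetero", "janickei"):
    pairs.extend(gen_pair_logs(params, pairing_type))
write_event_log(pairs, out / "pair_events.csv")

drops = gen_drops(params)
write_event_log(drops, out / "drop_events.csv")
with open(out / "drop_metadata.csv", "w") as fh:
    fh.write("drop_id,chamber_id,excluded,exclusion_reason\n")
    for d in drops:
        fh.write(f"{d.drop_id},{d.chamber_id},{int(d.excluded)},"
                 f"{d.exclusion_reason or ''}\n")

write_tps(gen_stylets(params), out / "stylets.tps")
params.to_yaml(out / "params_used.yaml")

print(f"wrote {len(pairs)} pair logs, {len(drops)} drops "
      f"and 72 stylet configurations to {out}/")
print("analyse them with: macromate traits / matechoice / morpho, "
      "or the other example scripts")
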