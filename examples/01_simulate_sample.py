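"""Generate one synthetic tumor sample with known truth labels.

The generator implants a chromothriptic chromosome, a breakage-fusion-bridge
chromosome and a circular double-minute amplicon into a 22-chromosome toy
genome, adds scattered background rearrangements, kataegis foci on a sparse
SNV background, and telomeric/random read mixtures.
"""

from chromocat import SimulationParams, simulate_sample

params = SimulationParams(seed=7, n_chromothripsis_chroms=1, n_bfb_chroms=1)
bundle, truth = simulate_sample(params, sample_id="demo")

print(f"sample {bundle.sample_id}: {len(bundle.svs)} SVs, {len(bundle.snvs)} SNVs")
events = {c: l for c, l in truth.chrom_labels.items() if l != "none"}
print(f"implanted events: {events}")
print(f"planted kataegis foci: {len(truth.kataegis_foci)}")
print(f"planted DM fragments: {len(truth.dm_fragments)} "
      f"({sum(f['end'] - f['start'] for f in truth.dm_fragments):,} bp total)")
# The truth labels are what the detectors in the other examples must recover.
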