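"""Arm usage, predominant-arm calls and cross-condition arm switching.

Runs the arm-switch preset (two conditions standing in for two species),
computes per-locus 5p/3p usage and flags loci whose relative arm usage
differs more than 10-fold between conditions.
"""

from mirkit import armprofile, simdata, workflow

cfg = simdata.scenario_presets()["arm_switch"]
cfg.reads_per_library = 20_000
res = simdata.generate(cfg, seed=1)
alignments = workflow.map_libraries(res.libraries, res.genome)
loci = {l.locus_id: l for l in res.loci if l.chrom in res.genome.sequences}

records = {}
for lib in ("anopheles_rep1", "aedes_rep1"):
    for spec in cfg.loci:
        if spec.rna_class != "miRNA" or "decoy" in spec.name:
            continue
        records[(spec.name, lib)] = armprofile.arm_usage_from_reads(
            loci[spec.name], alignments[lib], lib)

mean_prop, pooled = armprofile.global_arm_bias(
    [r for (n, lib), r in records.items() if lib == "anopheles_rep1"])
print(f"mean 5p proportion: {mean_prop:.3f} (pooled variant {pooled:.3f})")

for name in ("mir-1175", "mir-31", "mir-305", "mir-sim1"):
    a = records[(name, "anopheles_rep1")]
    b = records[(name, "aedes_rep1")]
    call = armprofile.detect_arm_switch_between(a, b, context="species_pair")
    print(f"{name}: ratios {a.ratio:.2f} vs {b.ratio:.2f} "
          f"(calls {a.call}/{b.call}), fold {call.fold_difference:.1f}, "
          f"switched={call.switched}")

# The locus panel is 3'-biased on average (mean 5p proportion ~0.4). The two
# planted switchers cross the 10-fold threshold between conditions; the
# balanced locus and the stable one do not.
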