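"""Random annotated-locus fixtures for network oracle tests."""

from ringscan.core_model import (
    Cas10Annotation,
    EffectorAnnotation,
    GeneFeature,
    Locus,
    RNAnnotation,
)

RN_POOL = ["Crn1", "Crn2", "Crn3", "Csx15", "Csx16", "Csx20"]
EFF_POOL = ["Csx1", "Csm6", "Csm6-2", "Can1", "Can2", "Cami1", "Cam1", "NucC"]


def random_annotated_loci(rng, max_loci=12):
    loci = []
    for i in range(int(rng.integers(0, max_loci))):
        anchor = GeneFeature(f"L{i}_cas10", "G", "c1", 10_000, 12_100, "+", "M" * 700)
        loc = Locus(
            locus_id=f"L{i}",
            genome_id="G",
            contig_id="c1",
            cas10=Cas10Annotation(anchor, True, False),
            cas_span=(10_000, 14_000),
            neighborhood=(4_000, 20_000),
        )
        for j, fam in enumerate(
            rng.choice(RN_POOL, size=int(rng.integers(0, 4)), replace=False)
        ):
            g = GeneFeature(f"L{i}_r{j}", "G", "c1", 15_000 + 600 * j, 15_449 + 600 * j, "+", "M" * 150)
            status = "fail" if rng.random() < 0.2 else "pass"
            loc.rns.append(
                RNAnnotation(
                    str(fam), g, 80.0, 1e-20,
                    screen_status=status,
                    missing_positions=((0, "H"),) if status == "fail" else (),
                )
            )
        for j, fam in enumerate(
            rng.choice(EFF_POOL, size=int(rng.integers(0, 3)), replace=False)
        ):
            g = GeneFeature(f"L{i}_e{j}", "G", "c1", 17_000 + 1500 * j, 18_199 + 1500 * j, "+", "M" * 400)
            loc.effectors.append(EffectorAnnotation(str(fam), g, 90.0, 1e-25))
        loci.append(loc)
    return loci
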