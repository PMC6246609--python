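#!/usr/bin/env python
"""Simulate the demonstration community and write it to results/fixture/.

Five genomes emulating an electrode-enriched community: a dominant
Geobacter-like pan-genome (core + two 2%-divergent substrains with additive
coverage and cross-linked contigs), a fermenter-like genome favoured under
open circuit, and a low-abundance competitor.  Cytochromes, pilins,
single-copy markers and stimulus-responsive genes are planted with known
truth; counts carry Poisson noise.
"""

import numpy as np

from stimulomics import simcom

SEED = 20180726 % (2 ** 31)
CONDS = list(simcom.DEFAULT_DESIGN.condition_ids)


def build_community() -> simcom.Community:
    specs = [
        simcom.GenomeSpec(
            "coreGeo", length=150_000, gc_target=0.58, n_orfs=24,
            n_marker_genes=8, cytc_plan=(3, 8, 12),
            pilin_plan=(simcom.PilinPlan(aromatic_count=9),),
            species="Geo1"),
        simcom.GenomeSpec("strainGeoB", parent="coreGeo", divergence=0.015,
                          length=150_000, species="Geo1"),
        simcom.GenomeSpec("strainGeoC", parent="coreGeo", divergence=0.02,
                          length=150_000, species="Geo1"),
        simcom.GenomeSpec(
            "fermLac", length=120_000, gc_target=0.38, n_orfs=20,
            n_marker_genes=8, cytc_plan=(1,),
            pilin_plan=(simcom.PilinPlan(
                aromatic_count=4,
                essential_flags=(True, True, False, True, False, False, True)),),
            species="Lac1"),
        simcom.GenomeSpec(
            "compMet", length=100_000, gc_target=0.48, n_orfs=18,
            n_marker_genes=8, cytc_plan=(2, 4), species="Met1"),
    ]
    # EET-active genomes gain abundance under poised conditions, the
    # fermenter under open circuit; the pan-genome core carries the summed
    # coverage of its substrains.
    strain_b = dict(zip(CONDS, [22.0, 24.0, 14.0, 12.0, 26.0]))
    strain_c = dict(zip(CONDS, [14.0, 15.0, 9.0, 8.0, 17.0]))
    depths = {
        "strainGeoB": strain_b,
        "strainGeoC": strain_c,
        "coreGeo": {c: strain_b[c] + strain_c[c] for c in CONDS},
        "fermLac": dict(zip(CONDS, [18.0, 16.0, 34.0, 40.0, 10.0])),
        "compMet": dict(zip(CONDS, [8.0, 7.0, 10.0, 11.0, 6.0])),
    }
    # Plant stimulus responses on annotated genes: multi-heme cytochromes
    # of the dominant Geobacter-like genome induced by AcPro and repressed
    # under open circuit; fermenter genes mirror-imaged.  A first build
    # (identical seed) locates the planted cytochrome ORF ids.
    preview = simcom.build_community(
        specs, depths, pan_groups={"coreGeo": ["strainGeoB", "strainGeoC"]},
        mean_contig_len=7000, noise="poisson", seed=SEED)
    cytc_core = list(preview.orfs.query(
        "genome == 'coreGeo' and kind == 'cytc'")["orf_id"])
    ferm = list(preview.orfs.query(
        "genome == 'fermLac' and kind == 'generic'")["orf_id"])
    met = list(preview.orfs.query(
        "genome == 'compMet' and kind == 'cytc'")["orf_id"])
    response_plan = {
        cytc_core[0]: ("AcPro", "positive", 8.0),
        cytc_core[1]: ("AcPro", "positive", 6.0),
        cytc_core[2]: ("OC", "negative", 7.0),
        ferm[0]: ("AcPro", "negative", 8.0),
        ferm[1]: ("OC", "positive", 6.0),
        met[0]: ("SP+", "negative", 5.5),
    }
    return simcom.build_community(
        specs, depths, response_plan=response_plan,
        pan_groups={"coreGeo": ["strainGeoB", "strainGeoC"]},
        mean_contig_len=7000, noise="poisson", seed=SEED)


def main() -> None:
    community = build_community()
    out = simcom.emit_fixture(community, "results/fixture")
    n_orfs = len(community.orfs)
    n_pilins = sum(community.orfs["kind"] == "pilin")
    n_cytc = sum(community.orfs["kind"] == "cytc")
    print(f"wrote fixture to {out}")
    print(f"  genomes: {len(community.genomes)}  contigs: "
          f"{len(community.contigs)}  ORFs: {n_orfs} "
          f"({n_cytc} planted cytochromes, {n_pilins} pilins)")
    print(f"  planted responders: {len(community.response_plan)}")


if __name__ == "__main__":
    main()
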