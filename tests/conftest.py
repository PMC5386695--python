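import numpy as np
import pandas as pd
import pytest

from supersilac import GeneratorConfig, SampleDesign, generate_experiment


@pytest.fixture
def six_sample_design() -> SampleDesign:
    """3 MM + 3 sPCL biological replicates, one technical replicate each."""
    rows = [
        {"sample_id": f"{g}_b{b}_t1", "group": g, "biological_replicate": b, "technical_replicate": 1}
        for g in ("MM", "sPCL")
        for b in (1, 2, 3)
    ]
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture
def tiny_protein_groups(tmp_path):
    """Five-row protein-groups table with one decoy, one contaminant and
    assorted missing cells, plus the matching 6-sample design file."""
    samples = [f"{g}_b{b}_t1" for g in ("MM", "sPCL") for b in (1, 2, 3)]
    header = ["Protein IDs", "Gene names", "Reverse", "Potential contaminant",
              "Only identified by site"]
    header += [f"Ratio H/L {s}" for s in samples]
    header += [f"LFQ intensity {s}" for s in samples]
    rows = [
        ["P10000", "GENEA", "", "", ""] + ["1.0", "1.1", "0.9", "2.0", "2.2", "1.9"]
        + ["1e6"] * 6,
        ["REV__P10001", "GENEB", "+", "", ""] + ["1.0"] * 6 + ["1e6"] * 6,
        ["CON__P10002", "GENEC", "", "+", ""] + ["1.0"] * 6 + ["1e6"] * 6,
        ["P10003", "GENED", "", "", ""] + ["NaN", "0.5", "0.4", "", "1.5", "1.6"]
        + ["0", "2e6", "3e6", "0", "4e6", "5e6"],
        ["P10004", "GENEE", "", "", "+"] + ["1.0"] * 6 + ["1e6"] * 6,
    ]
    pg = tmp_path / "proteinGroups.tsv"
    with open(pg, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    design = tmp_path / "design.tsv"
    pd.DataFrame(
        {
            "sample_id": samples,
            "group": ["MM"] * 3 + ["sPCL"] * 3,
            "biological_replicate": [1, 2, 3, 1, 2, 3],
            "technical_replicate": [1] * 6,
        }
    ).to_csv(design, sep="\t", index=False)
    return pg, design


@pytest.fixture(scope="session")
def small_experiment():
    """One deterministic synthetic experiment shared across tests."""
    cfg = GeneratorConfig(n_proteins=400, seed=11)
    return generate_experiment(cfg)
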