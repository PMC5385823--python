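import pytest

from tp53mir import preprocess, synthetic_data


@pytest.fixture(scope="session")
def default_design():
    return synthetic_data.default_design(seed=42)


@pytest.fixture(scope="session")
def default_collection(default_design):
    return synthetic_data.gen_microarray_collection(default_design)


@pytest.fixture(scope="session")
def cleaned_default(default_design, default_collection):
    cleaned, de, removed = preprocess.preprocess_pipeline(
        default_collection, default_design.genes, seed=42
    )
    return cleaned, de, removed


@pytest.fixture(scope="session")
def null_design():
    """Same shape as the default collection but with no planted effects."""
    return synthetic_data.PlantedDesign(
        planted_up=[], planted_down=[], effect_log2=0.0, seed=7
    )


@pytest.fixture(scope="session")
def null_collection(null_design):
    return synthetic_data.gen_microarray_collection(null_design)


@pytest.fixture(scope="session")
def planted_counts():
    """Default-scale count matrix with the six planted fold-changes."""
    fc = {g: 4.0 for g in ["BAK1", "DTL"]}
    fc.update({g: 0.25 for g in ["MEIS1", "LDOC1", "AGTR1", "TYMS"]})
    design = synthetic_data.CountDesign(seed=43, planted_fc=fc)
    counts, truth = synthetic_data.gen_count_matrix(design)
    return counts, truth


def brute_force_scan(seq: str, max_spacer: int = 13):
    """Independent oracle: test every (i, j) decamer pair by explicit IUPAC
    comparison against RRRCWWGYYY."""
    classes = {"R": "AG", "W": "AT", "Y": "CT", "C": "C", "G": "G"}
    pattern = "RRRCWWGYYY"
    seq = seq.upper()

    def is_decamer(i):
        if i + 10 > len(seq):
            return False
        return all(seq[i + k] in classes[pattern[k]] for k in range(10))

    hits = []
    for i in range(len(seq)):
        for j in range(len(seq)):
            spacer = j - i - 10
            if 0 <= spacer <= max_spacer and is_decamer(i) and is_decamer(j):
                hits.append((i, j, spacer))
    return sorted(hits)
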