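import numpy as np
import pytest

from cellscale import (
    build_correlation_table,
    generate_annotations,
    generate_design,
    generate_lipid_classes,
    generate_matrix,
    generate_network,
)


@pytest.fixture
def design_exact():
    """2x2 design, 2 replicates, radii exactly at the group means."""
    return generate_design(n_replicates=2, radius_cv=0.0, seed=0)


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study (seed 0) shared across read-only tests."""
    design = generate_design(seed=0)
    gene_matrix, gene_truth = generate_matrix(design, kind="gene", seed=0)
    met_matrix, met_truth = generate_matrix(
        design,
        n_positive=90,
        n_negative=36,
        n_null=174,
        n_genotype_shifted=0,
        kind="metabolite",
        seed=0,
    )
    return {
        "design": design,
        "gene_matrix": gene_matrix,
        "gene_truth": gene_truth,
        "met_matrix": met_matrix,
        "met_truth": met_truth,
        "gene_sets": generate_annotations(gene_truth, seed=0),
        "lipid_map": generate_lipid_classes(met_truth, seed=0),
        "network": generate_network(gene_truth, seed=0),
        "gene_table": build_correlation_table(gene_matrix, design),
        "met_table": build_correlation_table(
            met_matrix, design, pseudocount=0.0
        ),
    }
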