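import numpy as np
import pytest

from tmfc.community import CommunityAssignment, CommunityEnsemble, ModularityParams
from tmfc.networks import LayerMatrix, TemporalMultilayerNetwork, build_multilayer


def two_clique_layer() -> LayerMatrix:
    """Two disconnected unit-weight 3-cliques on 6 nodes."""
    w = np.zeros((6, 6))
    for tri in ([0, 1, 2], [3, 4, 5]):
        for i in tri:
            for j in tri:
                if i != j:
                    w[i, j] = 1.0
    return LayerMatrix(weights=w, window_index=0)


@pytest.fixture
def two_clique_single() -> TemporalMultilayerNetwork:
    return TemporalMultilayerNetwork(layers=[two_clique_layer()], omega=0.0)


@pytest.fixture
def two_clique_duplex() -> TemporalMultilayerNetwork:
    layers = [two_clique_layer(), LayerMatrix(two_clique_layer().weights, 1)]
    return build_multilayer(layers, omega=0.5)


def random_multilayer(
    rng: np.random.Generator, n_nodes: int, n_layers: int, omega: float
) -> TemporalMultilayerNetwork:
    """Random symmetric non-negative layers for oracle comparisons."""
    layers = []
    for s in range(n_layers):
        w = rng.random((n_nodes, n_nodes))
        w = (w + w.T) / 2
        w[w < 0.3] = 0.0  # some sparsity, keeps degenerate cases in play
        np.fill_diagonal(w, 0.0)
        layers.append(LayerMatrix(weights=w, window_index=s))
    return TemporalMultilayerNetwork(layers=layers, omega=omega)


def ensemble_from_labels(*label_arrays) -> CommunityEnsemble:
    """Build an ensemble directly from node x layer label matrices."""
    assignments = [
        CommunityAssignment(labels=np.asarray(lab), q_value=0.0)
        for lab in label_arrays
    ]
    return CommunityEnsemble(assignments=assignments,
                             params=ModularityParams(n_repetitions=len(assignments)))
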