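import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_backbone_spec():
    """A very small backbone for fast training-path tests (56-px input)."""
    from meddgtn.wtbackbone import BackboneSpec, WTConvSpec, WTDenseBlockSpec

    return BackboneSpec(blocks=[WTDenseBlockSpec(num_layers=1, growth=4)],
                        stem_channels=4, final_channels=16, input_size=56,
                        wtconv=WTConvSpec(levels=1))


@pytest.fixture
def tiny_model(tiny_backbone_spec):
    """A minimal assembled model over 4 labels with seeded inputs."""
    from meddgtn.dame import AnnotationMatrix, build_correlation_graph
    from meddgtn.model import MedDGTN

    gen = np.random.default_rng(0)
    ann = AnnotationMatrix(
        values=(gen.random((12, 4)) < 0.5).astype(int) | np.eye(4, dtype=int)[
            gen.integers(0, 4, 12)],
        label_order=["aa", "bb", "cc", "dd"])
    N = build_correlation_graph(ann)
    H0 = gen.standard_normal((4, 30)) * 2.0
    model = MedDGTN(H0, N, backbone_spec=tiny_backbone_spec, k=1, heads=2,
                    d_h=8, gcn_hidden=16, seed=0)
    images = gen.random((6, 3, 56, 56))
    labels = (gen.random((6, 4)) < 0.5).astype(float)
    labels[labels.sum(axis=1) == 0, 0] = 1.0
    return model, images, labels
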