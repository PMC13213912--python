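import numpy as np
import pytest

from pqatlas.descriptors import parse_smiles
from pqatlas.pq import ProductQuantizer
from pqatlas.synthetic import BlobSpec, generate_mqn_blobs, generate_smiles_library


@pytest.fixture(scope="session")
def small_library():
    """200 valid drug-like SMILES records."""
    smiles = generate_smiles_library(200, seed=11)
    return [parse_smiles(s, id=i) for i, s in enumerate(smiles)]


@pytest.fixture(scope="session")
def blobs():
    """Well-separated labelled count-vector blobs (n=600, k=5)."""
    spec = BlobSpec(n=600, k=5, spread=1.0, separation=5.0, seed=21)
    X, labels, centers = generate_mqn_blobs(spec)
    return X, labels, centers


@pytest.fixture(scope="session")
def fitted_pq(blobs):
    """A quantizer trained on the blob fixture (L=32 keeps tests fast)."""
    X, _, _ = blobs
    return ProductQuantizer(n_codewords=32, random_state=5).fit(X)


@pytest.fixture(scope="session")
def blob_codes(blobs, fitted_pq):
    X, _, _ = blobs
    return fitted_pq.transform(X)


def sd_bruteforce(code_a, code_b, codebooks):
    """Independent SD oracle: decode both codes and measure directly."""
    m, L, d_sub = codebooks.shape
    total = 0.0
    for j in range(m):
        diff = codebooks[j][code_a[j]] - codebooks[j][code_b[j]]
        total += float(diff @ diff)
    return np.sqrt(total)
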