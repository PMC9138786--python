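"""Planted-signal synthetic worlds for offline, fully testable runs.

A world places drugs into communities and derives all three input tables
from the community structure, so every channel carries partially
redundant, statistically recoverable signal:

* interactions — independent Bernoulli per unordered pair with
  probability ``p_in`` inside a community and ``p_out`` across,
* receptor profiles — each community is enriched for its own contiguous
  receptor block per function type (association probability 0.8 in-block,
  0.05 off-block),
* SMILES-like strings — drawn from a 20-symbol alphabet whose symbol
  frequencies are biased per community.

``p_in == p_out`` gives a null world with no planted structure; shuffling
labels with :func:`gen_null_labels` gives a permutation null on any
world.  Everything is reproducible byte-for-byte from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: 20-symbol SMILES-like alphabet (includes the two-letter halogens so the
#: atomwise tokenizer is exercised)
SMILES_ALPHABET = ["C", "c", "N", "n", "O", "o", "S", "s", "P", "F",
                   "I", "Cl", "Br", "(", ")", "=", "#", "1", "2", "3"]


@dataclass
class PlantedWorld:
    """A synthetic study population with known generative structure."""

    drugs: pd.DataFrame         # drug_id, smiles
    edges: pd.DataFrame         # drug_id_a, drug_id_b
    associations: pd.DataFrame  # drug_id, receptor_id, function_type
    community: dict             # drug_id -> community index
    params: dict = field(default_factory=dict)

    @property
    def drug_ids(self) -> list[str]:
        return sorted(self.drugs["drug_id"])


def gen_world(n_drugs: int = 200, n_communities: int = 4,
              p_in: float = 0.2, p_out: float = 0.02, n_types: int = 3,
              receptors_per_type: int = 50, p_assoc_in: float = 0.8,
              p_assoc_out: float = 0.05, seed: int = 0) -> PlantedWorld:
    """Generate a community-structured world with planted signal.

    Community assignment is balanced (drug ``i`` to community
    ``i % n_communities``); all randomness flows from ``seed``.
    """
    if not (0.0 <= p_out <= p_in <= 1.0):
        raise ValueError("probabilities must satisfy 0 <= p_out <= p_in <= 1")
    if not (0.0 <= p_assoc_out <= 1.0 and 0.0 <= p_assoc_in <= 1.0):
        raise ValueError("association probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"D{i:04d}" for i in range(n_drugs)]
    comm = np.arange(n_drugs) % n_communities

    # interactions: independent Bernoulli per unordered pair
    iu, ju = np.triu_indices(n_drugs, k=1)
    same = comm[iu] == comm[ju]
    p = np.where(same, p_in, p_out)
    keep = rng.random(len(iu)) < p
    edges = pd.DataFrame({
        "drug_id_a": [ids[i] for i in iu[keep]],
        "drug_id_b": [ids[j] for j in ju[keep]],
    })

    # receptor profiles: block-enriched per community and type
    rows = []
    block = max(receptors_per_type // n_communities, 1)
    for t in range(n_types):
        type_name = f"type{t}"
        for d in range(n_drugs):
            k = comm[d]
            lo = min(k * block, receptors_per_type - 1)
            hi = min(lo + block, receptors_per_type)
            probs = np.full(receptors_per_type, p_assoc_out)
            probs[lo:hi] = p_assoc_in
            hits = np.where(rng.random(receptors_per_type) < probs)[0]
            rows.extend((ids[d], f"{type_name}_r{r:03d}", type_name)
                        for r in hits)
    associations = pd.DataFrame(rows, columns=["drug_id", "receptor_id",
                                               "function_type"])

    # SMILES-like strings with community-biased symbol frequencies
    V = len(SMILES_ALPHABET)
    smiles = []
    for d in range(n_drugs):
        k = comm[d]
        w = np.ones(V)
        w[[(k * 5 + j) % V for j in range(5)]] = 4.0
        w /= w.sum()
        length = rng.integers(24, 72)
        toks = rng.choice(V, size=length, p=w)
        smiles.append("".join(SMILES_ALPHABET[t] for t in toks))
    drugs = pd.DataFrame({"drug_id": ids, "smiles": smiles})

    params = dict(n_drugs=n_drugs, n_communities=n_communities, p_in=p_in,
                  p_out=p_out, n_types=n_types,
                  receptors_per_type=receptors_per_type,
                  p_assoc_in=p_assoc_in, p_assoc_out=p_assoc_out, seed=seed)
    return PlantedWorld(drugs=drugs, edges=edges, associations=associations,
                        community={ids[i]: int(comm[i])
                                   for i in range(n_drugs)},
                        params=params)


def write_world(world: PlantedWorld, out_dir) -> Path:
    """Write drugs.tsv, edges.tsv, associations.tsv and world.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    world.drugs.to_csv(out / "drugs.tsv", sep="\t", index=False)
    world.edges.to_csv(out / "edges.tsv", sep="\t", index=False)
    world.associations.to_csv(out / "associations.tsv", sep="\t",
                              index=False)
    with open(out / "world.json", "w") as fh:
        json.dump({"params": world.params, "community": world.community},
                  fh, indent=2, sort_keys=True)
    return out


def gen_null_labels(labels, seed: int = 0) -> np.ndarray:
    """Permute a label vector (class balance preserved, signal destroyed)."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    return labels[rng.permutation(len(labels))]
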