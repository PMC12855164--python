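import datetime as dt

import numpy as np
import pandas as pd
import pytest

from ednasurvey.io_model import (
    DetectionMatrix,
    SampleRecord,
    TaxonDetection,
)


def make_matrix(positives, substrates=None, seasons=None, locations=None,
                n_replicates=8, scope="combined"):
    """Build a DetectionMatrix from a 2D array of positive-replicate counts."""
    positives = np.asarray(positives, dtype=int)
    S, E = positives.shape
    species = [f"sp{i}" for i in range(S)]
    eids = [f"e{j}" for j in range(E)]
    events = pd.DataFrame(
        {
            "location": locations or ["L1"] * E,
            "substrate": substrates or ["water"] * E,
            "season": seasons or ["wet"] * E,
            "date": [dt.date(2023, 3, 10) + dt.timedelta(days=j) for j in range(E)],
            "n_replicates": n_replicates,
        },
        index=pd.Index(eids, name="event_id"),
    )
    pos = pd.DataFrame(positives, index=species, columns=eids)
    pos.index.name = "species"
    return DetectionMatrix(pos, events, scope)


def random_matrix(rng, n_species=None, n_events=None, max_replicates=8,
                  substrates=("water", "sediment", "soil")):
    """Random small matrix for oracle-equivalence sweeps."""
    S = n_species or int(rng.integers(1, 11))
    E = n_events or int(rng.integers(2, 11))
    pos = rng.integers(0, max_replicates + 1, size=(S, E))
    subs = [substrates[int(i)] for i in rng.integers(0, len(substrates), size=E)]
    seas = [("wet", "dry")[int(i)] for i in rng.integers(0, 2, size=E)]
    locs = [f"L{int(i)}" for i in rng.integers(0, 3, size=E)]
    return make_matrix(pos, substrates=subs, seasons=seas, locations=locs,
                       n_replicates=max_replicates)


@pytest.fixture
def two_event_samples():
    """16 replicate samples: 8 water + 8 sediment, one day, one location."""
    samples = []
    for sub in ("water", "sediment"):
        for r in range(1, 9):
            samples.append(
                SampleRecord(
                    sample_id=f"{sub}{r}",
                    event_id=f"L1|{sub}|2023-03-10",
                    location="L1",
                    substrate=sub,
                    season="wet",
                    date=dt.date(2023, 3, 10),
                    replicate_index=r,
                    volume_ml=450.0 if sub == "water" else None,
                )
            )
    return samples


def det(sample_id, taxon, primer="12SV5", reads=100, rank="species"):
    return TaxonDetection(sample_id=sample_id, primer=primer,
                          taxon_name=taxon, rank=rank, read_count=reads)
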