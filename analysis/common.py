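"""Shared plumbing for the numbered analysis scripts.

Every script operates on the same simulated deployment pushed through the
full pipeline.  The heavy steps (simulation, track fitting) are cached under
``scratch/analysis/`` so the scripts can be run and re-run independently;
the cache directory is disposable and not part of the repository.
"""

from __future__ import annotations

import pickle
import warnings
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
CACHE = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 0


def get_run(seed: int = SEED):
    """Return (sim_result, track_set, classified_dives) for the default
    deployment, building and caching it on first use."""
    from sealdive import pipeline as P
    from sealdive import simulate as S

    CACHE.mkdir(parents=True, exist_ok=True)
    path = CACHE / f"run_seed{seed}.pkl"
    if path.exists():
        with open(path, "rb") as fh:
            return pickle.load(fh)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = S.simulate(S.SimConfig(seed=seed))
        tracks = P.fit_tracks(res.argos, res.dry)
        located = P.locate_dives(tracks, res.dives)
        classified = P.classify_located_dives(located, res.bathy)
    bundle = (res, tracks, classified)
    with open(path, "wb") as fh:
        pickle.dump(bundle, fh)
    return bundle


def write_table(df, name: str) -> Path:
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / name
    df.to_csv(out, index=False, float_format="%.6g")
    print(f"wrote {out.relative_to(ROOT)}  ({len(df)} rows)")
    return out
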