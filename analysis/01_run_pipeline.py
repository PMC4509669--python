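"""Simulate the deployment, fit the movement models, and summarize the
telemetry processing: per-animal data volumes, speed-filter removals, and
geolocation accuracy of the dive positions against the simulated truth."""

import numpy as np
import pandas as pd

from common import get_run, write_table


def main() -> None:
    res, tracks, classified = get_run()
    truth = res.truth.dives
    plane = res.plane

    xe, ye = plane.to_xy(classified["lon"].to_numpy(),
                         classified["lat"].to_numpy())
    xt, yt = plane.to_xy(truth["lon"].to_numpy(), truth["lat"].to_numpy())
    err_km = np.hypot(xe - xt, ye - yt)
    err = pd.DataFrame({"animal_id": classified["animal_id"].to_numpy(),
                        "err_km": err_km})

    rows = []
    for animal, rep in tracks.reports.items():
        model = tracks.models[animal]
        e = err.loc[err["animal_id"] == animal, "err_km"]
        hauled_h = sum(b - a for a, b in model.haulouts_s) / 3600.0
        rows.append({
            "animal_id": animal,
            "argos_locations": rep.n_input,
            "removed_speed": rep.n_removed_speed,
            "removed_spike": rep.n_removed_spike,
            "kept": rep.n_kept,
            "dives": int((classified["animal_id"] == animal).sum()),
            "ctd_casts": int(res.casts.loc[res.casts["animal_id"] == animal,
                                           "cast_id"].nunique()),
            "haulout_hours": round(hauled_h, 1),
            "ctcrw_beta_per_h": round(model.beta, 4),
            "ctcrw_sigma": round(model.sigma, 4),
            "median_dive_position_error_km": round(float(e.median()), 3),
            "p90_dive_position_error_km": round(float(e.quantile(0.9)), 3),
        })
    write_table(pd.DataFrame(rows), "track_processing.csv")


if __name__ == "__main__":
    main()
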