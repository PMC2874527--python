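"""Round-trippable text serialisation for parameter sets, designs,
trajectories and control-analysis outputs.

All tabular output is UTF-8 CSV/TSV with stable reaction/species id headers;
floats are written with 17 significant digits so that load(save(x)) == x.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .linlog import (ElasticityMatrix, Parameterization, PerturbationDesign,
                     ReferenceState, Trajectory, elasticity_pattern)
from .network import NetworkModel


def load_printed_partial_fcc() -> pd.DataFrame:
    """Published reference table of partial flux control coefficients.

    Columns: flux_id, enzyme_id, mediator_id, value, printed_total.  Used as
    input to the decomposition identity (total = direct term + mediator sum).
    """
    from importlib import resources
    path = resources.files("linlogccm") / "data" / "printed_partial_fcc.tsv"
    return pd.read_csv(str(path), sep="\t")


def save_parameterization(p: Parameterization, path: str | Path,
                          meta: dict | None = None) -> None:
    payload = {
        "meta": meta or {},
        "elasticities": [
            {"reaction": rid, "species": sid, "value": v}
            for (rid, sid), v in sorted(p.elasticities.values.items())],
        "J0": p.reference.J0,
        "c0": p.reference.c0,
        "enzyme_levels": p.enzyme_levels,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_parameterization(path: str | Path,
                          model: NetworkModel | None = None
                          ) -> Parameterization:
    with open(path) as fh:
        payload = json.load(fh)
    values = {(e["reaction"], e["species"]): float(e["value"])
              for e in payload["elasticities"]}
    pattern = (elasticity_pattern(model) if model is not None
               else sorted(values))
    return Parameterization(
        elasticities=ElasticityMatrix(pattern=pattern, values=values),
        reference=ReferenceState(J0=payload["J0"], c0=payload["c0"]),
        enzyme_levels=payload.get("enzyme_levels", {}))


def save_design(design: PerturbationDesign, path: str | Path) -> None:
    payload = {
        "post_perturbation_extracellular":
            design.post_perturbation_extracellular,
        "time_grid": list(design.time_grid),
        "observed": list(design.observed),
        "replicates": design.replicates,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_design(path: str | Path) -> PerturbationDesign:
    with open(path) as fh:
        payload = json.load(fh)
    return PerturbationDesign(
        post_perturbation_extracellular=payload[
            "post_perturbation_extracellular"],
        time_grid=tuple(payload["time_grid"]),
        observed=list(payload.get("observed", [])),
        replicates=int(payload.get("replicates", 3)))


def save_trajectory(traj: Trajectory, path: str | Path,
                    model: NetworkModel | None = None,
                    header_comment: str | None = None) -> None:
    frame = traj.to_frame(model)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False, float_format="%.17g")


def load_trajectory(path: str | Path) -> Trajectory:
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    times = np.sort(frame["time_min"].unique())
    species = list(dict.fromkeys(frame["species_id"]))
    values = np.full((times.size, len(species)), np.nan)
    ti = {t: i for i, t in enumerate(times)}
    si = {s: j for j, s in enumerate(species)}
    for row in frame.itertuples(index=False):
        values[ti[row.time_min], si[row.species_id]] = row.value_normalized
    return Trajectory(times=times, species_ids=species, values=values)
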