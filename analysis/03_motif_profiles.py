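#!/usr/bin/env python
"""Motif-anchored average profiles: activator occupancy, nucleosome dyads, TBP.

Runs the demo pipeline at reduced depth (1e5 fragments x 2 replicates) and
writes the averaged profiles around the 5' motifs: induced/uninduced
activator occupancy, MNase dyad density (showing the NDR flanked by the
-1/+1 nucleosomes and their partial eviction on induction), and the TBP
summit-localization profile peaking downstream of the motifs.  Profiles are
written every 5 bp to keep the tables compact.
"""

from pathlib import Path

from ndrchip.aggregate import profile_to_frame
from ndrchip.pipeline import simulate_and_run

OUT = Path(__file__).resolve().parent.parent / "results"
DEPTH = 100_000


def main(seed: int = 1) -> None:
    out = simulate_and_run(seed=seed, n_fragments=DEPTH)
    OUT.mkdir(parents=True, exist_ok=True)

    profiles = {
        "profile_gcn4_wt_i": out["gcn4_profile_wt_i"],
        "profile_dyads_wt_u": out["dyad_profile"],
        "profile_dyads_wt_i": out["dyad_profile_induced"],
        "profile_tbp_wt_i": out["tbp_profile"],
    }
    for name, profile in profiles.items():
        frame = profile_to_frame(profile).iloc[::5]
        frame.to_csv(OUT / f"{name}.tsv", sep="\t", index=False)

    cfg = out["truth"].config
    dy_u, dy_i = out["dyad_profile"], out["dyad_profile_induced"]
    plus_u = dy_u.argmax_position(cfg.plus_one_offset - 50, cfg.plus_one_offset + 50)
    gp = out["gcn4_profile_wt_i"]
    near = abs(gp.positions) <= 300
    centroid = (gp.positions[near] * gp.mean[near]).sum() / gp.mean[near].sum()
    print(f"activator occupancy peak centered {centroid:+.1f} bp from the motif "
          "(signal centroid within +-300 bp; planted at 0)")
    print(f"+1 dyad peak (uninduced) at +{plus_u} bp "
          f"(planted +{cfg.plus_one_offset})")
    at_plus1 = dy_i.mean[dy_i.positions == plus_u][0] / \
        dy_u.mean[dy_u.positions == plus_u][0]
    print(f"induction reduces +1 dyad density to {at_plus1:.2f} of uninduced "
          "(promoter nucleosome eviction)")
    tbp_peak = out["tbp_profile"].argmax_position(0, 300)
    print(f"TBP summit profile peaks at +{tbp_peak} bp downstream of the motif "
          f"(planted +{cfg.tbp_offset})")
    print(f"profiles written under {OUT}")


if __name__ == "__main__":
    main()
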