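"""Label-driven registration and activation-peak spread.

Simulates a functional cohort (left hemisphere), builds the thresholded
group reference from the binary segment labels, registers every
participant to it, and compares the spatial spread (median pairwise
geodesic distance) of the ventral-larynx activation peaks with and
without registration.  A ratio below 1 means anatomical alignment
explains part of the functional variability.
"""

import warnings

from sulcmorph import CohortSpec, RegistrationConfig, build_reference, make_cohort
from sulcmorph.peaks import compare_registrations

warnings.filterwarnings("ignore")

cohort = [p for p in make_cohort(CohortSpec(n_struct=20, n_func=12, seed=8,
                                            attach_volumes=False))
          if p.hemisphere == "left"]
ref = build_reference([p.labels for p in cohort], cohort[0].mesh, threshold=0.4)

df = compare_registrations(cohort, ref, config=RegistrationConfig.fast(),
                           methods=("none", "labels"), hemispheres=("left",))
print(df.to_string(index=False))
# median_distance_mm: spread of each effector's peaks across participants
# on the common sphere (n_pairs = n_peaks*(n_peaks-1)/2 distances)

vl = df[df.effector == "larynx_ventral"].set_index("method").median_distance_mm
print(f"\nventral larynx spread: none={vl['none']:.1f} mm, "
      f"labels={vl['labels']:.1f} mm (ratio {vl['labels']/vl['none']:.2f})")
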