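# gpilead

Stereotactic analysis of deep-brain-stimulation (DBS) leads implanted in the
internal globus pallidus (GPi), the surgical target for dystonia and for
motor symptoms of Parkinson's disease (PD).

Given the two commissural landmarks (AC, PC), two CT-visible points per
implanted lead, the programmed stimulation configuration, and a segmentation
mask of the GPi, the package answers the questions a functional-neurosurgery
group asks after a bilateral implantation series:

* Where is each lead, and where is its **active contact**, in AC-PC
  coordinates (LAT / AP / VERT relative to the midcommissural point)?
* How far is the lead from the **intended target** at the target's depth
  (the in-plane targeting error `d = sqrt(ΔAP² + ΔLAT²)`)?
* How do **atlas-based** standard coordinates (LAT 20–22 mm, AP 2–3 mm,
  VERT 1–2 mm inferior) differ from **direct** targets chosen on the
  patient's own MRI?
* Where does the active contact sit **inside the GPi**?  The contact C is
  projected onto the structure's anterior–posterior, medial–lateral and
  ventral–dorsal boundary segments at its axial level, giving three
  normalized indices

  ```
  AP-index = |AS| / |AP|      (> 0.5 : posterior)
  ML-index = |MS| / |ML|
  VD-index = |VS| / |VD|      (< 0.5 : ventral)
  ```

  where A, P, M, L, V, D are the six boundary points and S the orthogonal
  projection of C onto each segment.  The posteroventral ("motor") GPi
  corresponds to AP-index > 0.5 with VD-index < 0.5.

The lead model is the quadripolar Medtronic 3389 (contacts 1.5 mm long,
0.5 mm apart, numbered 0 distal to 3; bilateral implants address the second
lead as 8–11).  Every point on a lead is `P = T + k·u` with T the tip and
`u` the unit vector toward a second, more dorsal shaft point; for a bipolar
pair of adjacent stimulated contacts the active point is the geometric
center of the two contact centers.

Because no per-lead coordinates are published for the packaged cohort, a
first-class synthetic-data module simulates bilateral cohorts whose target
distributions match the published subgroup means/SDs, with ellipsoidal
GPi/GPe/internal-capsule masks whose analytic parameters serve as ground
truth for every pipeline stage.

## Worked example

```python
import gpilead as g

frame = g.build_frame(ac=[0, 12.5, 0], pc=[0, -12.5, 0],
                      midsagittal_normal=[1, 0, 0])

# a vertical right-hemisphere lead, tip 5 mm below the AC-PC plane
obs = g.LeadObservation(tip=[20.0, 2.0, -5.0], shaft=[20.0, 2.0, 20.0])
contacts = g.active_contact_point(g.contact_centers(obs), "9–10+")
print(contacts.active_point)            # [20.    2.    0.25]

target = g.StereoCoordinates(lat=19.2, ap=1.4, vert=-2.0, hemisphere="right")
err = g.targeting_error(target, obs, frame)
print(round(err.d_euclid, 3))           # 1.0  (0.8 lateral, 0.6 anterior)

print(g.atlas_target(third_ventricle_width=6.0, acpc_length=24.0))
# StereoCoordinates(lat=21.0, ap=2.0, vert=-1.5, hemisphere='right')
```

Cohort-level analyses live under `analysis/` and write their tables to
`results/`:

```
$ python analysis/01_cohort_demographics.py
13 patients (7 m / 6 f), 26 leads
age 57.6 +/- 20.1 years
active contact GPi: 19/26 leads (73%)
active contact GPi/GPe: 5/26 leads (19%)
active contact IC/GPi: 2/26 leads (8%)
```

`02_simulate_cohort.py` generates the default synthetic cohort,
`03_localize_and_index.py` runs the reconstruction + indexing pipeline on
it, `04_target_comparison.py` summarizes atlas-vs-direct differences and
targeting errors, and `05_subgroup_stats.py` runs the dystonia-vs-PD
contrasts (unpaired pooled-variance t-test, KS normality check).

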