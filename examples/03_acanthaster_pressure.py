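"""How many crown-of-thorns sea stars would cancel a site's gross production?

The predation model combines a search-circle attack rate (rising steeply with
coral cover), a Holling type-II ingestion rate, and the transect sea-star
density. Inverting it gives the smallest belt count at which predation alone
would consume everything the site calcifies.
"""

from reefbudget.acanthaster import AcanthasterParams, density_threshold

params = AcanthasterParams()
print(f"outbreak convention: > {params.outbreak_density_ha:.0f} sea stars ha^-1\n")

print("cover%  gross  count/belt  per-100m2   per-ha")
for cover, gross in [(10.0, 2.0), (20.0, 4.0), (30.0, 6.0), (50.0, 8.0), (80.0, 10.0)]:
    thr = density_threshold(cover, gross, mean_coral_density=1.4)
    per_ha = thr.count_per_100m2 * 100.0
    flag = "  <- outbreak-level" if per_ha > params.outbreak_density_ha else ""
    print(
        f"{cover:5.0f}  {gross:5.1f}  {thr.count:10d}  {thr.count_per_100m2:9.2f}"
        f"  {per_ha:7.0f}{flag}"
    )

print(
    "\nPer-individual consumption rises steeply with coral cover (shorter"
    "\nsearch distances), so high-cover sites need far fewer sea stars to"
    "\nlose their whole gross production. All of these counts dwarf the"
    "\n30 ha^-1 outbreak convention: realistic outbreaks trim the budget"
    "\nrather than zero it."
)
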