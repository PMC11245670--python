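# CSV schemas

All tables are plain CSV with ISO dates (`YYYY-MM-DD`). These are the
schemas emitted by `lrspipe simulate` and consumed by the cleaning and
analysis stages.

## cows.csv
| column | type | meaning |
|---|---|---|
| cow_id | str | unique animal identifier |
| farm_id | str | herd the cow belongs to |
| birth_date | date | date of birth |
| dam_id | str | mother's cow_id; empty if unknown |
| entry_date | date | date the cow entered the herd (equals birth_date for home-bred animals) |
| exit_date | date | date the cow left the herd; empty if unknown |

## calvings.csv
| column | type | meaning |
|---|---|---|
| cow_id | str | calving cow |
| farm_id | str | herd |
| calving_date | date | calving event date |
| parity | int | 1-based calving number |

## milk.csv (raw recordings)
| column | type | meaning |
|---|---|---|
| cow_id | str | recorded cow |
| date | date | test-day date |
| yield | float | daily milk yield, kg |
| fat_pct / protein_pct / lactose_pct | float | composition, % |
| scc | float | somatic cell count, ×1,000 cells/mL |

The cleaned milk table adds `lactation` (1-based, by bracketing calving
dates) and `dim` (days in milk, 0 on the calving date).

## events.csv
| column | type | meaning |
|---|---|---|
| cow_id | str | affected cow |
| date | date | event date |
| event_type | str | `mastitis`, `lameness`, or `treatment` |
| raw_text | str | free-text record (product name for treatments) |

After `match_treatments` the table adds `category` (`mastitis`,
`lameness`, `antimicrobial`, `anti_inflammatory`, `vaccine`, `other`,
`unmatched`), `dry_cow_flag`, `matched_product` and `match_score`.

## weather.csv
| column | type | meaning |
|---|---|---|
| station_id | str | weather station |
| date | date | observation day |
| t_max | float | daily maximum temperature, °C |
| dewpoint | float | daily dewpoint, °C |
| latitude / longitude | float | station location, degrees |

Derived columns `rh_min` (%) and `thi_max` (index points) are added by
the THI stage.

## farms.csv
`farm_id`, `latitude`, `longitude` (point location, degrees).

## products.csv
`name` (licensed product name), `category` (`antimicrobial`,
`anti_inflammatory`, `vaccine`).

## truth/ (generator ground truth)
* `cows.csv` — per-cow `latent`, `farm_eff`, `dam_eff`, `injected`,
  generation (0 = founder), and the true window exposures
  (`mean_thi_t1/t2/t3`, plus any event-exposure features referenced by
  the injected effects).
* `effects.csv` — injected effect sizes (`feature`, `coefficient`).
* `variance_components.csv` — true farm/dam/residual SDs.
* `pedigree.csv` — `cow_id`, `dam_id`, `granddam_id`.
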