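# Default activity-code classification map.
#
# This is a deliberately small, documented default covering common diary
# codes in a Trial-ICATUS-like dialect.  It is NOT the authentic published
# code lookup; analyses of real survey data should supply the complete
# mapping in this same format (`timeuse-coda classify --activity-map ...`).
#
# direct:     code -> PA | SB | SLEEP  (sleep is only ever assigned here;
#             naps count as sleep regardless of clock time)
# met_rules:  ordered; first match wins.  `pattern` is a glob on the code,
#             `field`/`value` optionally qualify by occupation or location.
#             Resulting category: SB if met <= met_threshold else PA.
# met_threshold: conventional 1.5 MET sedentary boundary; PA is any-intensity
#             movement, so everything awake above the threshold is PA.

met_threshold: 1.5
strict: true
fallback: SB

direct:
  "0111": SLEEP     # night sleep
  "0112": SLEEP     # naps and incidental sleep
  "0210": SB        # eating and drinking
  "0311": PA        # personal hygiene and dressing (light ambulatory)
  "0611": PA        # food preparation
  "0621": PA        # cleaning and upkeep of dwelling
  "0631": PA        # laundry and clothes care
  "0711": PA        # shopping for household
  "0811": PA        # physical care of children
  "1211": SB        # socialising and conversation
  "1311": PA        # participating in sports and exercise
  "1411": SB        # reading
  "1421": SB        # watching television and video
  "1431": SB        # listening to radio and audio
  "1441": SB        # computer and device use

met_rules:
  # employment-related work: MET depends on reported occupation
  - {pattern: "11*", field: occupation, value: office_clerk, met: 1.3}
  - {pattern: "11*", field: occupation, value: professional, met: 1.5}
  - {pattern: "11*", field: occupation, value: sales_service, met: 2.3}
  - {pattern: "11*", field: occupation, value: agricultural, met: 4.0}
  - {pattern: "11*", field: occupation, value: craft_trades, met: 3.5}
  - {pattern: "11*", met: 2.0}                    # work, occupation unknown
  # travel: MET depends on reported mode (recorded in the location field)
  - {pattern: "18*", field: location, value: on_foot, met: 3.5}
  - {pattern: "18*", field: location, value: bicycle, met: 6.0}
  - {pattern: "18*", field: location, value: motor_vehicle, met: 1.3}
  - {pattern: "18*", met: 1.3}                    # travel, mode unknown
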