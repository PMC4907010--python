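# Demo ED site: 19 beds (two further beds reserved for trauma calls are not
# part of the general capacity) and a nurse roster by clock band.  Band ends
# are inclusive minutes; the night band wraps midnight.
bed_capacity: 19
nurse_bands:
  weekday:
    - {start: "07:00", end: "11:59", nurses: 7}
    - {start: "12:00", end: "19:59", nurses: 8}
    - {start: "20:00", end: "22:59", nurses: 7}
    - {start: "23:00", end: "06:59", nurses: 4}
  weekend:
    - {start: "07:00", end: "10:59", nurses: 7}
    - {start: "11:00", end: "19:59", nurses: 8}
    - {start: "20:00", end: "22:59", nurses: 7}
    - {start: "23:00", end: "06:59", nurses: 5}
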