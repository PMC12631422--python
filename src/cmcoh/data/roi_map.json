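{
 "PMC": {
  "left": [
   "E30",
   "E36",
   "E41",
   "E42",
   "E43",
   "E49",
   "E50",
   "E56",
   "E57"
  ],
  "right": [
   "E197",
   "E204",
   "E205",
   "E206",
   "E212",
   "E213",
   "E214",
   "E215",
   "E224"
  ]
 },
 "M1": {
  "left": [
   "E51",
   "E52",
   "E58",
   "E59",
   "E60",
   "E65",
   "E66"
  ],
  "right": [
   "E155",
   "E164",
   "E182",
   "E183",
   "E184",
   "E195",
   "E196"
  ]
 },
 "Pr": {
  "left": [
   "E76",
   "E77",
   "E85",
   "E86",
   "E87",
   "E88",
   "E89",
   "E96",
   "E97",
   "E98",
   "E99",
   "E100",
   "E106",
   "E107",
   "E108",
   "E109",
   "E110",
   "E118"
  ],
  "right": [
   "E127",
   "E128",
   "E129",
   "E130",
   "E140",
   "E141",
   "E142",
   "E151",
   "E152",
   "E153",
   "E160",
   "E161",
   "E162",
   "E163",
   "E169",
   "E170",
   "E171",
   "E172"
  ]
 },
 "SMA": {
  "midline": [
   "E6",
   "E7",
   "E8",
   "E15",
   "E16",
   "E17",
   "E23",
   "E24",
   "E198",
   "E207"
  ]
 }
}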