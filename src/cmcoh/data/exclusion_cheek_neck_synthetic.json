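{
 "description": "Synthetic stand-in exclusion list: the 62 most inferior electrodes of the standard GSN HydroCel 256 montage (cheek/neck ring). The study's actual exclusion list is unpublished; only the retained count (194) is fixed.",
 "excluded": [
  "E73",
  "E82",
  "E91",
  "E92",
  "E93",
  "E102",
  "E103",
  "E104",
  "E111",
  "E112",
  "E120",
  "E121",
  "E133",
  "E134",
  "E145",
  "E146",
  "E156",
  "E165",
  "E166",
  "E174",
  "E175",
  "E187",
  "E188",
  "E189",
  "E199",
  "E200",
  "E201",
  "E208",
  "E209",
  "E216",
  "E217",
  "E218",
  "E226",
  "E227",
  "E228",
  "E229",
  "E230",
  "E231",
  "E232",
  "E233",
  "E234",
  "E235",
  "E236",
  "E237",
  "E238",
  "E239",
  "E240",
  "E241",
  "E242",
  "E243",
  "E244",
  "E245",
  "E246",
  "E247",
  "E248",
  "E249",
  "E250",
  "E251",
  "E252",
  "E254",
  "E255",
  "E256"
 ]
}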