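{
 "type": "FeatureCollection",
 "features": [
  {
   "type": "Feature",
   "properties": {
    "id": "MF"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       0,
       0
      ],
      [
       986,
       0
      ],
      [
       986,
       500
      ],
      [
       0,
       500
      ],
      [
       0,
       0
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "id": "NF"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       1000,
       0
      ],
      [
       1764,
       0
      ],
      [
       1764,
       500
      ],
      [
       1000,
       500
      ],
      [
       1000,
       0
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "id": "MG"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       1800,
       0
      ],
      [
       1878,
       0
      ],
      [
       1878,
       500
      ],
      [
       1800,
       500
      ],
      [
       1800,
       0
      ]
     ]
    ]
   }
  },
  {
   "type": "Feature",
   "properties": {
    "id": "NG"
   },
   "geometry": {
    "type": "Polygon",
    "coordinates": [
     [
      [
       1900,
       0
      ],
      [
       2196,
       0
      ],
      [
       2196,
       500
      ],
      [
       1900,
       500
      ],
      [
       1900,
       0
      ]
     ]
    ]
   }
  }
 ]
}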