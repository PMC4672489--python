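"""Script-based access over the RESTful/JSON API.

Starts the API server on a background thread over an in-memory store,
uploads a batch of points by POST and reads hourly statistics and the
stream summary back — the same documents the library returns in-process.
"""

import json
import threading
import urllib.request

from fieldstore import SensorStore
from fieldstore.api import make_server

store = SensorStore()
store.create_entity("user", "u")
store.create_entity("experiment", "e", "u")
store.create_entity("node", "n", "u~e")
store.create_entity("stream", "temp", "u~e~n", attrs={"unit": "degC"})

server = make_server(store)  # port 0 -> ephemeral
base = f"http://127.0.0.1:{server.server_address[1]}"
threading.Thread(target=server.serve_forever, daemon=True).start()


def call(method, path, body=None):
    data = json.dumps(body).encode() if body is not None else None
    req = urllib.request.Request(base + path, data=data, method=method)
    with urllib.request.urlopen(req) as resp:
        return json.loads(resp.read())


points = [[t, 15.0 + (t % 7200) / 1000.0] for t in range(0, 7200, 60)]
upload = call("POST", "/streams/u~e~n~temp/data", {"points": points})
print(f"uploaded: {upload}")

hourly = call("GET", "/streams/u~e~n~temp/data?level=1-hour&from=0&to=7200")
for row in hourly:
    print(f"hour {row['start']}: n={row['count']} mean={row['mean']:.3f} "
          f"min={row['min']:.2f} max={row['max']:.2f}")

summary = call("GET", "/streams/u~e~n~temp/summary")
print(f"overall count: {summary['overall']['count']}")

server.shutdown()
server.server_close()
# Two hourly windows of 60 points each; the overall row counts all 120.
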